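"""Simulators for the four canonical landscape regimes.

* **additive** — F(g) = baseline + Σ_i δ_i·presence_i: a maximally smooth
  landscape; every mutation's ΔF is constant, so global-epistasis scatters
  are flat.
* **house-of-cards** — every genotype's fitness drawn iid from a normal
  distribution: a maximally rugged landscape; regression to the mean gives
  every mutation a slope near −1, R² near 0.5 and an intercept near the
  distribution mean.
* **pairwise** — the additive model plus interaction terms ε_ij added when
  both members of a pair are present; with a single ε₁₂ this is the sparse
  regime whose slope for mutation 1 is proportional to ε₁₂/δ₂.
* **latent** — an additive latent variable λ (the fitness potential) pushed
  through a nonlinear transform, F = exp(λ) (convex) or F = 1 − exp(−λ)
  (concave saturating).  Exponential transforms make every ΔF-vs-F_B
  relation exactly linear, with closed-form slope and intercept.

All parameters (δ, ε) are on the {0,1} presence scale; the ±1 Walsh
coefficients are obtained by transforming the simulated landscape, never by
assumed conversion formulas.  Every simulator is deterministic given its
spec (the house-of-cards spec carries its own seed), and specs can be read
from plain key-value YAML config files.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import yaml

from .landscape import Landscape, LandscapeError

__all__ = [
    "AdditiveSpec",
    "PairwiseSpec",
    "HoCSpec",
    "LatentSpec",
    "simulate_additive",
    "simulate_hoc",
    "simulate_pairwise",
    "simulate_latent",
    "latent_closed_form_slope",
    "enumerate_genotypes",
    "load_spec",
    "TRANSFORMS",
]

TRANSFORMS = {
    "convex_exp": np.exp,
    "concave_saturating": lambda lam: 1.0 - np.exp(-lam),
}
_TRANSFORM_ALIASES = {"convex": "convex_exp", "concave": "concave_saturating"}


def enumerate_genotypes(n_loci: int) -> np.ndarray:
    """All 2^N genotypes in binary-index order (locus k ↔ bit k)."""
    idx = np.arange(2**n_loci)
    return ((idx[:, None] >> np.arange(n_loci)) & 1).astype(np.uint8)


def _default_names(n: int) -> tuple[str, ...]:
    return tuple(f"m{k + 1}" for k in range(n))


@dataclasses.dataclass
class AdditiveSpec:
    """Purely additive landscape: per-locus effects δ_i on the {0,1} scale."""

    locus_names: tuple[str, ...]
    baseline: float = 0.0
    effects: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.locus_names = tuple(self.locus_names)
        self.effects = tuple(float(e) for e in self.effects)
        if len(self.effects) != len(self.locus_names):
            raise LandscapeError(
                f"{len(self.effects)} effects for {len(self.locus_names)} loci"
            )
        if not all(math.isfinite(e) for e in self.effects):
            raise LandscapeError("effects must be finite")


@dataclasses.dataclass
class PairwiseSpec(AdditiveSpec):
    """Additive model plus sparse pairwise interactions ε_ij.

    ``interactions`` maps unordered locus pairs (names or indices) to the
    interaction value added when both loci are present.
    """

    interactions: Mapping = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        norm: dict[tuple[int, int], float] = {}
        for pair, value in dict(self.interactions).items():
            i, j = (self._resolve(p) for p in pair)
            if i == j:
                raise LandscapeError(f"self-interaction on locus {pair}")
            key = (min(i, j), max(i, j))
            if key in norm:
                raise LandscapeError(f"duplicate interaction for pair {pair}")
            norm[key] = float(value)
        self.interactions = norm

    def _resolve(self, locus) -> int:
        if isinstance(locus, (int, np.integer)):
            if not 0 <= locus < len(self.locus_names):
                raise LandscapeError(f"locus index {locus} out of range")
            return int(locus)
        try:
            return self.locus_names.index(str(locus))
        except ValueError:
            raise LandscapeError(f"unknown locus {locus!r}") from None


@dataclasses.dataclass
class HoCSpec:
    """House-of-cards: iid Normal(mean, sd) fitness for every genotype."""

    locus_names: tuple[str, ...]
    mean: float = 1.0
    sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.locus_names = tuple(self.locus_names)
        if not self.sd > 0:
            raise LandscapeError("sd must be > 0")


@dataclasses.dataclass
class LatentSpec(AdditiveSpec):
    """Additive latent variable λ pushed through a named nonlinear transform."""

    transform: str = "concave_saturating"

    def __post_init__(self) -> None:
        super().__post_init__()
        self.transform = _TRANSFORM_ALIASES.get(self.transform, self.transform)
        if self.transform not in TRANSFORMS:
            raise LandscapeError(
                f"unknown transform {self.transform!r}; "
                f"choose from {sorted(TRANSFORMS)}"
            )


# ---------------------------------------------------------------------------
# simulators


def _additive_field(spec: AdditiveSpec) -> tuple[np.ndarray, np.ndarray]:
    G = enumerate_genotypes(len(spec.locus_names))
    values = spec.baseline + G @ np.asarray(spec.effects, dtype=float)
    return G, values


def simulate_additive(spec: AdditiveSpec) -> Landscape:
    """Complete landscape with F(g) = baseline + Σ δ_i·presence_i."""
    G, F = _additive_field(spec)
    return Landscape(spec.locus_names, G, F)


def simulate_pairwise(spec: PairwiseSpec) -> Landscape:
    """Additive landscape plus ε_ij whenever both loci of a pair are present."""
    G, F = _additive_field(spec)
    for (i, j), eps in spec.interactions.items():
        F = F + eps * (G[:, i] * G[:, j])
    return Landscape(spec.locus_names, G, F)


def simulate_hoc(spec: HoCSpec) -> Landscape:
    """Maximally rugged landscape: 2^N iid Normal(mean, sd) draws.

    Identical spec (including seed) yields a bit-identical landscape.
    """
    n = len(spec.locus_names)
    rng = np.random.default_rng(spec.seed)
    F = rng.normal(spec.mean, spec.sd, size=2**n)
    return Landscape(spec.locus_names, enumerate_genotypes(n), F)


def simulate_latent(spec: LatentSpec) -> Landscape:
    """Nonlinear transform of an additive latent variable λ."""
    G, lam = _additive_field(spec)
    return Landscape(spec.locus_names, G, TRANSFORMS[spec.transform](lam))


def latent_closed_form_slope(
    transform: str, delta_lambda: float
) -> tuple[float, float]:
    """Exact (slope, intercept) of ΔF vs F_B under an exponential transform.

    convex_exp:          ΔF = (e^{δλ} − 1)·F_B
                         → slope e^{δλ} − 1, intercept 0.
    concave_saturating:  ΔF = (1 − e^{−δλ})·(1 − F_B)
                         → slope −(1 − e^{−δλ}), intercept 1 − e^{−δλ}.
    """
    transform = _TRANSFORM_ALIASES.get(transform, transform)
    if transform == "convex_exp":
        return math.exp(delta_lambda) - 1.0, 0.0
    if transform == "concave_saturating":
        shift = 1.0 - math.exp(-delta_lambda)
        return -shift, shift
    raise LandscapeError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# spec config files


def load_spec(path: str | Path):
    """Read a simulator spec from a key-value YAML config.

    Keys: ``model`` (additive|pairwise|hoc|latent), ``loci`` (names list or
    a count), ``baseline``, ``effects``, ``interactions`` (mapping like
    ``"m1,m2": 0.12``), ``transform``, ``mean``, ``sd``, ``seed``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return spec_from_mapping(raw)


def spec_from_mapping(raw: Mapping):
    model = str(raw.get("model", "")).lower()
    loci = raw.get("loci")
    if isinstance(loci, int):
        names = _default_names(loci)
    elif isinstance(loci, Sequence) and not isinstance(loci, str):
        names = tuple(str(x) for x in loci)
    elif "effects" in raw:
        names = _default_names(len(raw["effects"]))
    else:
        raise LandscapeError("spec needs 'loci' (names or a count)")

    if model == "additive":
        return AdditiveSpec(names, float(raw.get("baseline", 0.0)), raw["effects"])
    if model == "pairwise":
        interactions = {
            tuple(str(k).split(",")): v
            for k, v in (raw.get("interactions") or {}).items()
        }
        return PairwiseSpec(
            names, float(raw.get("baseline", 0.0)), raw["effects"], interactions
        )
    if model == "hoc":
        return HoCSpec(
            names,
            float(raw.get("mean", 1.0)),
            float(raw.get("sd", 0.2)),
            int(raw.get("seed", 0)),
        )
    if model == "latent":
        return LatentSpec(
            names,
            float(raw.get("baseline", 0.0)),
            raw["effects"],
            transform=str(raw.get("transform", "concave_saturating")),
        )
    raise LandscapeError(f"unknown model {model!r}")


def simulate(spec) -> Landscape:
    """Dispatch on spec type; single entry point used by the CLI."""
    if isinstance(spec, LatentSpec):
        return simulate_latent(spec)
    if isinstance(spec, PairwiseSpec):
        return simulate_pairwise(spec)
    if isinstance(spec, HoCSpec):
        return simulate_hoc(spec)
    if isinstance(spec, AdditiveSpec):
        return simulate_additive(spec)
    raise LandscapeError(f"not a simulator spec: {type(spec).__name__}")
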