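"""Walsh (Fourier) expansion of a fitness landscape.

Any function on the hypercube {−1, +1}^N decomposes uniquely as

    F = F̄ + Σ_i f_i x_i + Σ_{j>i} f_ij x_i x_j + Σ_{k>j>i} f_ijk x_i x_j x_k + …

where x_i = ±1 encodes absence/presence of mutation i (derived from the
stored {0,1} genotypes via x = 2·presence − 1).  The coefficients are taken
in the uniform-measure orthonormal basis — each one is the mean over all 2^N
genotypes of F times the corresponding sign character.  This normalisation
is what makes the background-averaged identities used by
:mod:`epiland.epistasis` exact on pairwise landscapes:

    f_ij = ⟨ε_ij⟩ / 4      and      f_j − f_ij = ⟨δF_j⟩_B(i) / 2 .

The exact transform requires a complete landscape and is computed either by
a fast butterfly (``method="fast"``, O(N·2^N)) or by the direct sign-sum
(``method="direct"``, the slow oracle the fast path is checked against).
For incomplete landscapes an explicit least-squares estimation mode
(``method="lstsq"``) fits coefficients up to ``max_order`` by minimising
squared reconstruction error over the measured genotypes; its result is an
estimate and is flagged as such.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .landscape import Landscape, LandscapeError

__all__ = [
    "WalshExpansion",
    "WalshRegression",
    "to_walsh",
    "from_walsh",
    "truncate",
    "save_expansion",
    "load_expansion",
]


def fwht(values: np.ndarray) -> np.ndarray:
    """Unnormalised fast Walsh–Hadamard transform.

    Returns W with W[s] = Σ_p values[p]·(−1)^{popcount(p & s)} for indices
    p, s over 2^N.  Input length must be a power of two.
    """
    a = np.asarray(values, dtype=float)
    n = a.shape[0]
    m = n.bit_length() - 1
    if n != 1 << m:
        raise ValueError("length must be a power of two")
    a = a.reshape((2,) * m) if m else a.copy()
    for axis in range(m):
        lo = a.take(0, axis=axis)
        hi = a.take(1, axis=axis)
        a = np.stack([lo + hi, lo - hi], axis=axis)
    return a.reshape(-1)


def _subset_masks(n_loci: int, max_order: int) -> list[tuple[tuple[int, ...], int]]:
    out = []
    for order in range(1, max_order + 1):
        for subset in combinations(range(n_loci), order):
            mask = 0
            for k in subset:
                mask |= 1 << k
            out.append((subset, mask))
    return out


def _characters(G: np.ndarray, subsets: list[tuple[int, ...]]) -> np.ndarray:
    """Design matrix of sign characters Π_{i∈S} x_i over genotype rows."""
    X = 2.0 * G - 1.0
    cols = [np.ones(G.shape[0])]
    cols += [np.prod(X[:, list(s)], axis=1) for s in subsets]
    return np.column_stack(cols)


@dataclasses.dataclass
class WalshExpansion:
    """Interaction-coefficient representation of a landscape.

    ``coefficients`` maps sorted locus-index tuples (size ≥ 1) to the
    coefficient value; the mean term F̄ is kept separately.  ``estimated``
    marks coefficients obtained by least squares from an incomplete
    landscape rather than by the exact transform.
    """

    locus_names: tuple[str, ...]
    mean_term: float
    coefficients: dict[tuple[int, ...], float]
    max_order: int
    estimated: bool = False

    def __post_init__(self) -> None:
        n = len(self.locus_names)
        for subset in self.coefficients:
            if not subset or tuple(sorted(set(subset))) != subset:
                raise LandscapeError(f"malformed subset key {subset!r}")
            if subset[-1] >= n:
                raise LandscapeError(f"subset {subset!r} outside locus range")
            if len(subset) > self.max_order:
                raise LandscapeError(
                    f"subset {subset!r} exceeds max_order={self.max_order}"
                )

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def coefficient(self, *loci: int | str) -> float:
        idx = tuple(
            sorted(
                self.locus_names.index(l) if isinstance(l, str) else int(l)
                for l in loci
            )
        )
        return self.coefficients.get(idx, 0.0)

    def subset_names(self, subset: tuple[int, ...]) -> str:
        return ",".join(self.locus_names[k] for k in subset)


def to_walsh(
    landscape: Landscape,
    max_order: int | None = None,
    method: str = "fast",
) -> WalshExpansion:
    """Expand a landscape into Walsh interaction coefficients.

    Subsets larger than ``max_order`` (default N) are dropped.  ``fast``
    and ``direct`` require a complete landscape; ``lstsq`` estimates the
    truncated expansion from whatever genotypes are measured.
    """
    n = landscape.n_loci
    if max_order is None:
        max_order = n
    if not 1 <= max_order <= n:
        raise LandscapeError(f"max_order must be in [1, {n}]")

    if method in ("fast", "direct"):
        if not landscape.is_complete:
            raise LandscapeError(
                "exact Walsh transform requires a complete landscape; "
                "use method='lstsq' for an estimate"
            )
        dense = landscape.dense_fitness()
        if method == "fast":
            W = fwht(dense) / dense.shape[0]
            mean_term = float(W[0])
            coeffs = {}
            for subset, mask in _subset_masks(n, max_order):
                sign = -1.0 if len(subset) % 2 else 1.0
                coeffs[subset] = float(sign * W[mask])
        else:  # direct sign-sum: the oracle
            G = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)
            X = 2.0 * G - 1.0
            mean_term = float(dense.mean())
            coeffs = {
                subset: float(np.mean(dense * np.prod(X[:, list(subset)], axis=1)))
                for subset, _ in _subset_masks(n, max_order)
            }
        return WalshExpansion(landscape.locus_names, mean_term, coeffs, max_order)

    if method == "lstsq":
        subsets = [s for s, _ in _subset_masks(n, max_order)]
        A = _characters(landscape.genotypes, subsets)
        if A.shape[0] < A.shape[1]:
            raise LandscapeError(
                f"{A.shape[0]} measured genotypes cannot identify "
                f"{A.shape[1]} coefficients; lower max_order"
            )
        beta, *_ = np.linalg.lstsq(A, landscape.fitness, rcond=None)
        coeffs = {s: float(b) for s, b in zip(subsets, beta[1:])}
        return WalshExpansion(
            landscape.locus_names, float(beta[0]), coeffs, max_order, estimated=True
        )

    raise LandscapeError(f"unknown transform method {method!r}")


def from_walsh(expansion: WalshExpansion) -> Landscape:
    """Evaluate an expansion forward into a complete landscape.

    Inverse of :func:`to_walsh` for full-order expansions of complete
    landscapes.  Uses the self-inverse property of the Hadamard kernel:
    placing (−1)^{|S|}·f_S at bitmask S and transforming once yields F.
    """
    n = expansion.n_loci
    signed = np.zeros(2**n)
    signed[0] = expansion.mean_term
    for subset, value in expansion.coefficients.items():
        mask = 0
        for k in subset:
            mask |= 1 << k
        signed[mask] = value if len(subset) % 2 == 0 else -value
    dense = fwht(signed)
    G = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(np.uint8)
    return Landscape(expansion.locus_names, G, dense)


def truncate(expansion: WalshExpansion, order: int) -> WalshExpansion:
    """Drop all interaction terms above ``order``; F̄ is unchanged."""
    if order < 1:
        raise LandscapeError("truncation order must be ≥ 1")
    if order > expansion.max_order:
        raise LandscapeError(
            f"cannot truncate to {order}: expansion holds order ≤ {expansion.max_order}"
        )
    coeffs = {s: v for s, v in expansion.coefficients.items() if len(s) <= order}
    return WalshExpansion(
        expansion.locus_names,
        expansion.mean_term,
        coeffs,
        order,
        estimated=expansion.estimated,
    )


# ---------------------------------------------------------------------------
# coefficients TSV


def save_expansion(
    expansion: WalshExpansion,
    path: str | Path,
    metadata: tuple[str, ...] = (),
    float_format: str = "%.17g",
) -> None:
    rows = [("", 0, expansion.mean_term)]
    for subset in sorted(expansion.coefficients, key=lambda s: (len(s), s)):
        rows.append(
            (expansion.subset_names(subset), len(subset), expansion.coefficients[subset])
        )
    df = pd.DataFrame(rows, columns=["subset", "order", "coefficient"])
    with open(path, "w") as fh:
        for line in metadata:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def load_expansion(path: str | Path, locus_names: tuple[str, ...]) -> WalshExpansion:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    mean_term = 0.0
    coeffs: dict[tuple[int, ...], float] = {}
    name_to_idx = {n: k for k, n in enumerate(locus_names)}
    for _, row in df.iterrows():
        subset_str = str(row["subset"]).strip()
        if subset_str == "":
            mean_term = float(row["coefficient"])
            continue
        try:
            subset = tuple(sorted(name_to_idx[n] for n in subset_str.split(",")))
        except KeyError as exc:
            raise LandscapeError(f"unknown locus in subset {subset_str!r}") from exc
        coeffs[subset] = float(row["coefficient"])
    max_order = max((len(s) for s in coeffs), default=1)
    return WalshExpansion(tuple(locus_names), mean_term, coeffs, max_order)


# ---------------------------------------------------------------------------
# estimator interface


class WalshRegression(BaseEstimator, RegressorMixin):
    """Walsh-basis regression of fitness on a binary genotype matrix.

    scikit-learn-style estimator: ``fit(X, y)`` with ``X`` an (M, N) 0/1
    presence matrix and ``y`` the fitness values; ``predict`` evaluates the
    fitted expansion on new genotypes, so it composes with sklearn model
    selection (e.g. cross-validating the choice of ``max_order`` on a
    partially measured landscape).

    Parameters
    ----------
    max_order : int or None
        Largest interaction order retained (None → N).
    method : {"exact", "direct", "lstsq"}
        "exact" (fast butterfly) and "direct" demand a complete landscape;
        "lstsq" least-squares-estimates the truncated expansion from any
        set of measured genotypes.

    Attributes
    ----------
    mean_term_ : float
    coefficients_ : dict mapping locus-index tuples to values
    expansion_ : WalshExpansion
    """

    def __init__(self, max_order: int | None = None, method: str = "exact"):
        self.max_order = max_order
        self.method = method

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_loci) matching y")
        names = tuple(f"m{k + 1}" for k in range(X.shape[1]))
        landscape = Landscape(names, X, y)
        method = {"exact": "fast"}.get(self.method, self.method)
        self.expansion_ = to_walsh(landscape, self.max_order, method=method)
        self.mean_term_ = self.expansion_.mean_term
        self.coefficients_ = dict(self.expansion_.coefficients)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X)
        subsets = sorted(self.coefficients_, key=lambda s: (len(s), s))
        A = _characters(X, subsets)
        beta = np.concatenate(
            [[self.mean_term_], [self.coefficients_[s] for s in subsets]]
        )
        return A @ beta
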