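"""Data model and I/O for combinatorial binary-locus fitness landscapes.

A landscape maps genotypes — presence/absence vectors over ``N`` named loci
(mutations, species, drugs, ...) — to a scalar fitness or function value in
caller-defined units.  Genotypes are stored in the {0, 1} encoding; the
±1 (Walsh) encoding is derived only inside :mod:`epiland.walsh` via
``x = 2·presence − 1``, so that a single canonical storage form avoids silent
sign errors.

Two plain-text dialects are supported:

* **wide** — one column per locus (cells 0/1) plus a literal ``fitness``
  column; the header names the loci and their order defines bit order.
* **genotype-string** — two columns, ``genotype`` (a string over {0,1},
  read left-to-right as locus 1..N) and ``fitness``.

Lines starting with ``#`` are metadata comments and are ignored on read.
Incomplete landscapes (fewer than 2^N genotypes measured) are first-class;
every averaging operation downstream skips unmeasurable terms and reports
the count actually used.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Landscape",
    "LandscapeError",
    "BackgroundSet",
    "load_landscape",
    "save_landscape",
    "backgrounds_of",
    "fitness_effect",
    "pairwise_epistasis",
]

FITNESS_COLUMN = "fitness"
GENOTYPE_COLUMN = "genotype"


class LandscapeError(ValueError):
    """A landscape file or data structure violates the data model."""


def _as_genotype(g: Sequence[int] | str, n_loci: int) -> np.ndarray:
    """Coerce a genotype given as string/sequence to a validated uint8 vector."""
    if isinstance(g, str):
        if not set(g) <= {"0", "1"}:
            raise LandscapeError(f"genotype string {g!r} contains non-binary characters")
        arr = np.frombuffer(g.encode(), dtype=np.uint8) - ord("0")
    else:
        arr = np.asarray(g)
        if arr.ndim != 1 or not np.isin(arr, (0, 1)).all():
            raise LandscapeError(f"genotype {g!r} is not a flat 0/1 vector")
        arr = arr.astype(np.uint8)
    if arr.shape[0] != n_loci:
        raise LandscapeError(
            f"genotype has {arr.shape[0]} loci, landscape has {n_loci}"
        )
    return arr


@dataclasses.dataclass
class Landscape:
    """A (possibly incomplete) fitness landscape over binary loci.

    Parameters
    ----------
    locus_names
        Ordered, unique locus identifiers; their order defines bit order.
    genotypes
        ``(M, N)`` array over {0, 1}, one row per measured genotype.
    fitness
        ``(M,)`` array of finite fitness values, arbitrary units.
    """

    locus_names: tuple[str, ...]
    genotypes: np.ndarray
    fitness: np.ndarray

    def __post_init__(self) -> None:
        self.locus_names = tuple(str(n) for n in self.locus_names)
        if len(set(self.locus_names)) != len(self.locus_names):
            raise LandscapeError("duplicate locus names")
        if not self.locus_names:
            raise LandscapeError("a landscape needs at least one locus")
        G = np.asarray(self.genotypes)
        if G.ndim != 2 or G.shape[1] != len(self.locus_names):
            raise LandscapeError(
                f"genotype matrix shape {G.shape} does not match "
                f"{len(self.locus_names)} loci"
            )
        if not np.isin(G, (0, 1)).all():
            raise LandscapeError("genotype matrix contains non-binary values")
        self.genotypes = G.astype(np.uint8)
        F = np.asarray(self.fitness, dtype=float)
        if F.shape != (G.shape[0],):
            raise LandscapeError("fitness vector length does not match genotypes")
        if not np.isfinite(F).all():
            bad = int(np.flatnonzero(~np.isfinite(F))[0])
            raise LandscapeError(f"non-finite fitness at row {bad + 1}")
        self.fitness = F
        self._index: dict[bytes, int] = {}
        for row, g in enumerate(self.genotypes):
            key = g.tobytes()
            if key in self._index:
                raise LandscapeError(
                    f"duplicate genotype {''.join(map(str, g))} at row {row + 1}"
                )
            self._index[key] = row
        self._dense: np.ndarray | None = None

    # -- basic geometry -------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def n_genotypes(self) -> int:
        return self.genotypes.shape[0]

    @property
    def is_complete(self) -> bool:
        """True iff all 2^N genotypes are measured."""
        return self.n_genotypes == 2 ** self.n_loci

    def locus_index(self, locus: int | str) -> int:
        """Resolve a locus given by name or 0-based index."""
        if isinstance(locus, (int, np.integer)):
            if not 0 <= locus < self.n_loci:
                raise LandscapeError(f"locus index {locus} out of range")
            return int(locus)
        try:
            return self.locus_names.index(str(locus))
        except ValueError:
            raise LandscapeError(f"unknown locus {locus!r}") from None

    def index_of(self, genotype: Sequence[int] | str) -> int:
        """Row index of a genotype, or −1 if unmeasured."""
        g = _as_genotype(genotype, self.n_loci)
        return self._index.get(g.tobytes(), -1)

    def __contains__(self, genotype: Sequence[int] | str) -> bool:
        return self.index_of(genotype) >= 0

    def fitness_of(self, genotype: Sequence[int] | str) -> float:
        row = self.index_of(genotype)
        if row < 0:
            g = _as_genotype(genotype, self.n_loci)
            raise LandscapeError(
                f"genotype {''.join(map(str, g))} is not measured"
            )
        return float(self.fitness[row])

    def dense_fitness(self) -> np.ndarray:
        """Fitness ordered by binary genotype index (locus k ↔ bit k).

        Only defined for complete landscapes; cached after first call.
        """
        if not self.is_complete:
            raise LandscapeError("dense ordering requires a complete landscape")
        if self._dense is None:
            weights = (1 << np.arange(self.n_loci)).astype(np.int64)
            idx = self.genotypes.astype(np.int64) @ weights
            dense = np.empty(2 ** self.n_loci)
            dense[idx] = self.fitness
            self._dense = dense
        return self._dense

    # -- construction / conversion --------------------------------------

    @classmethod
    def from_dict(
        cls,
        entries: dict[str, float],
        locus_names: Sequence[str] | None = None,
    ) -> "Landscape":
        """Build from a ``{genotype string: fitness}`` mapping."""
        strings = list(entries)
        n = len(strings[0]) if strings else 0
        if locus_names is None:
            locus_names = tuple(f"m{k + 1}" for k in range(n))
        G = np.array([_as_genotype(s, n) for s in strings], dtype=np.uint8)
        F = np.array([entries[s] for s in strings], dtype=float)
        return cls(tuple(locus_names), G, F)

    def genotype_strings(self) -> list[str]:
        return ["".join(map(str, g)) for g in self.genotypes]

    def to_frame(self, dialect: str = "wide") -> pd.DataFrame:
        if dialect == "wide":
            df = pd.DataFrame(self.genotypes, columns=list(self.locus_names))
            df[FITNESS_COLUMN] = self.fitness
            return df
        if dialect == "genotype-string":
            return pd.DataFrame(
                {GENOTYPE_COLUMN: self.genotype_strings(), FITNESS_COLUMN: self.fitness}
            )
        raise LandscapeError(f"unknown dialect {dialect!r}")


@dataclasses.dataclass
class BackgroundSet:
    """The backgrounds B(i) on which a focal mutation may be added.

    Each background lacks the focal locus and has its counterpart B+i
    measured, so the fitness effect ΔF_i = F_{B+i} − F_B is defined on
    every member.
    """

    focal: str
    backgrounds: np.ndarray  # (K, N) over {0, 1}

    def __len__(self) -> int:
        return self.backgrounds.shape[0]


# ---------------------------------------------------------------------------
# file I/O


def _detect_dialect(columns: Sequence[str]) -> str:
    if set(columns) == {GENOTYPE_COLUMN, FITNESS_COLUMN}:
        return "genotype-string"
    return "wide"


def load_landscape(path: str | Path, dialect: str = "auto") -> Landscape:
    """Read a landscape table (TSV; ``#`` lines ignored) and validate it.

    Raises :class:`LandscapeError` naming the offending row for duplicate
    genotypes, non-binary locus values, or missing/unparseable fitness.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise LandscapeError(f"cannot read landscape file {path}: {exc}") from exc
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if dialect == "auto":
        dialect = _detect_dialect(cols)
    if FITNESS_COLUMN not in cols:
        raise LandscapeError(f"no '{FITNESS_COLUMN}' column in {path}")

    fitness = np.empty(len(df))
    for row, cell in enumerate(df[FITNESS_COLUMN]):
        try:
            fitness[row] = float(cell)
        except (TypeError, ValueError):
            raise LandscapeError(
                f"missing or unparseable fitness at row {row + 1}"
            ) from None

    if dialect == "genotype-string":
        strings = df[GENOTYPE_COLUMN].astype(str).str.strip()
        lengths = strings.str.len().unique()
        if len(lengths) != 1:
            raise LandscapeError("genotype strings have inconsistent lengths")
        n = int(lengths[0])
        locus_names = tuple(f"m{k + 1}" for k in range(n))
        G = np.empty((len(df), n), dtype=np.uint8)
        for row, s in enumerate(strings):
            try:
                G[row] = _as_genotype(s, n)
            except LandscapeError as exc:
                raise LandscapeError(f"row {row + 1}: {exc}") from None
    elif dialect == "wide":
        locus_names = tuple(c for c in cols if c != FITNESS_COLUMN)
        if not locus_names:
            raise LandscapeError("wide table has no locus columns")
        G = np.empty((len(df), len(locus_names)), dtype=np.uint8)
        for col_i, name in enumerate(locus_names):
            for row, cell in enumerate(df[name]):
                cell = str(cell).strip()
                if cell not in ("0", "1"):
                    raise LandscapeError(
                        f"non-binary value {cell!r} for locus {name!r} at row {row + 1}"
                    )
                G[row, col_i] = int(cell)
    else:
        raise LandscapeError(f"unknown dialect {dialect!r}")

    try:
        return Landscape(locus_names, G, fitness)
    except LandscapeError as exc:
        raise LandscapeError(f"{path}: {exc}") from None


def save_landscape(
    landscape: Landscape,
    path: str | Path,
    dialect: str = "wide",
    metadata: Iterable[str] = (),
) -> None:
    """Write a landscape as TSV with optional ``#``-prefixed metadata lines.

    Fitness is written at full precision (``%.17g``) so that
    ``load(save(L))`` reproduces ``L`` bit-exactly.
    """
    for name in landscape.locus_names:
        if any(ch in name for ch in "\t\n\r#"):
            raise LandscapeError(
                f"locus name {name!r} contains the column delimiter or a comment char"
            )
    df = landscape.to_frame(dialect)
    with open(path, "w") as fh:
        for line in metadata:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# elementary effect / epistasis evaluations


def backgrounds_of(landscape: Landscape, focal: int | str) -> BackgroundSet:
    """All genetic backgrounds B(i) where the focal mutation may be added.

    A background qualifies when it lacks the focal mutation and its
    counterpart with the mutation added is also measured.  For a complete
    landscape there are exactly 2^(N−1) of them.
    """
    fi = landscape.locus_index(focal)
    rows = []
    for g in landscape.genotypes:
        if g[fi]:
            continue
        partner = g.copy()
        partner[fi] = 1
        if partner.tobytes() in landscape._index:
            rows.append(g)
    backgrounds = (
        np.array(rows, dtype=np.uint8)
        if rows
        else np.empty((0, landscape.n_loci), dtype=np.uint8)
    )
    return BackgroundSet(landscape.locus_names[fi], backgrounds)


def fitness_effect(
    landscape: Landscape, focal: int | str, background: Sequence[int] | str
) -> float:
    """ΔF_i(B) = F_{B+i} − F_B for a focal mutation on one background."""
    fi = landscape.locus_index(focal)
    b = _as_genotype(background, landscape.n_loci)
    if b[fi]:
        raise LandscapeError(
            f"background already contains focal locus {landscape.locus_names[fi]!r}"
        )
    plus = b.copy()
    plus[fi] = 1
    return landscape.fitness_of(plus) - landscape.fitness_of(b)


def pairwise_epistasis(
    landscape: Landscape,
    i: int | str,
    j: int | str,
    background: Sequence[int] | str,
) -> float:
    """Four-corner epistasis ε_ij(B) = F_{B+i+j} − F_{B+i} − F_{B+j} + F_B.

    Symmetric in i and j; zero everywhere on an additive landscape.
    """
    ii, jj = landscape.locus_index(i), landscape.locus_index(j)
    if ii == jj:
        raise LandscapeError("pairwise epistasis needs two distinct loci")
    b = _as_genotype(background, landscape.n_loci)
    if b[ii] or b[jj]:
        raise LandscapeError("background must lack both loci of the pair")
    corners = []
    for bits in ((0, 0), (1, 0), (0, 1), (1, 1)):
        g = b.copy()
        g[ii], g[jj] = bits
        row = landscape.index_of(g)
        if row < 0:
            raise LandscapeError(
                f"missing corner genotype {''.join(map(str, g))}"
            )
        corners.append(landscape.fitness[row])
    f00, f10, f01, f11 = corners
    return float(f11 - f10 - f01 + f00)
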