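"""Multi-environment trial (MET) tables, design matrices and the G+GE matrix.

A MET records a response (typically yield) for every genotype × environment ×
block combination.  The GGE (site regression) decomposition works on the
environment-centered matrix of cell means: subtracting each environment's mean
removes the environment main effect but keeps the genotype main effect inside
the bilinear part, which is what distinguishes GGE from AMMI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "METTable",
    "DesignSet",
    "GGEMatrix",
    "read_met_table",
    "met_from_frame",
    "build_design",
    "center_gge_matrix",
    "svd_gge",
    "subset_environments",
]

REQUIRED_COLUMNS = ("genotype", "environment", "block", "response")


class METValidationError(ValueError):
    """Raised when a MET table violates a structural invariant."""


@dataclass(frozen=True)
class METTable:
    """Long-format MET phenotype records plus derived counts.

    Attributes
    ----------
    records : pandas.DataFrame
        Columns ``genotype``, ``environment``, ``block`` (strings) and
        ``response`` (float), preserved in input order.
    genotypes, environments, blocks : list of str
        Sorted (lexicographic) unique level labels.
    """

    records: pd.DataFrame
    genotypes: list[str] = field(default_factory=list)
    environments: list[str] = field(default_factory=list)
    blocks: list[str] = field(default_factory=list)

    @property
    def v(self) -> int:
        return len(self.genotypes)

    @property
    def l(self) -> int:
        return len(self.environments)

    @property
    def b(self) -> int:
        return len(self.blocks)

    @property
    def r(self) -> int:
        """Replicates per genotype on complete data (blocks × environments)."""
        return self.b * self.l

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def t(self) -> int:
        """Maximal bilinear rank, min(v − 1, l)."""
        return min(self.v - 1, self.l)

    @property
    def y(self) -> np.ndarray:
        return self.records["response"].to_numpy(dtype=float)

    def cell_counts(self) -> pd.DataFrame:
        """v×l table of observation counts per (genotype, environment) cell."""
        counts = (
            self.records.groupby(["genotype", "environment"], observed=True)
            .size()
            .unstack(fill_value=0)
        )
        return counts.reindex(
            index=self.genotypes, columns=self.environments, fill_value=0
        )

    def is_complete(self) -> bool:
        return self.n == self.v * self.b * self.l


def met_from_frame(frame: pd.DataFrame) -> METTable:
    """Validate a long-format frame and wrap it as a :class:`METTable`."""
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise METValidationError(f"missing required column(s): {missing}")
    records = frame.loc[:, list(REQUIRED_COLUMNS)].copy()
    for col in ("genotype", "environment", "block"):
        records[col] = records[col].astype(str)
    bad = pd.to_numeric(records["response"], errors="coerce")
    if bad.isna().any():
        row = int(np.flatnonzero(bad.isna().to_numpy())[0])
        raise METValidationError(f"non-numeric response at input row {row}")
    records["response"] = bad.astype(float)
    records = records.reset_index(drop=True)

    dup = records.duplicated(subset=["genotype", "environment", "block"])
    if dup.any():
        key = records.loc[dup.idxmax(), ["genotype", "environment", "block"]]
        raise METValidationError(
            f"duplicated (genotype, environment, block) key: {tuple(key)}"
        )
    met = METTable(
        records=records,
        genotypes=sorted(records["genotype"].unique()),
        environments=sorted(records["environment"].unique()),
        blocks=sorted(records["block"].unique()),
    )
    if met.v < 2 or met.l < 2 or met.b < 1:
        raise METValidationError(
            f"need at least 2 genotypes, 2 environments, 1 block; "
            f"got v={met.v}, l={met.l}, b={met.b}"
        )
    return met


def read_met_table(
    path, *, sep: str | None = None, column_map: dict[str, str] | None = None
) -> METTable:
    """Read a delimited MET file (CSV default, tab accepted).

    Parameters
    ----------
    sep : str, optional
        Field delimiter; sniffed between ``,`` and tab when omitted.
    column_map : dict, optional
        Maps file header names to the canonical
        ``genotype/environment/block/response`` names.
    """
    frame = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if column_map:
        frame = frame.rename(columns=column_map)
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    return met_from_frame(frame)


@dataclass(frozen=True)
class DesignSet:
    """Incidence matrices for the linear-bilinear model.

    ``X1`` (n × b·l) indexes block-within-environment (environment-major,
    block-minor order), ``X2`` (n × l) the environment and ``Z`` (n × v) the
    genotype of every record.  Integer index vectors are kept alongside for
    fast sampler kernels.
    """

    X1: np.ndarray
    X2: np.ndarray
    Z: np.ndarray
    g_idx: np.ndarray
    e_idx: np.ndarray
    be_idx: np.ndarray


def build_design(met: METTable) -> DesignSet:
    """Build incidence matrices under the fixed lexicographic ordering."""
    g_pos = {g: i for i, g in enumerate(met.genotypes)}
    e_pos = {e: j for j, e in enumerate(met.environments)}
    b_pos = {b: k for k, b in enumerate(met.blocks)}
    g_idx = met.records["genotype"].map(g_pos).to_numpy()
    e_idx = met.records["environment"].map(e_pos).to_numpy()
    blk = met.records["block"].map(b_pos).to_numpy()
    be_idx = e_idx * met.b + blk  # environment-major, block-minor

    n = met.n
    X1 = np.zeros((n, met.b * met.l))
    X2 = np.zeros((n, met.l))
    Z = np.zeros((n, met.v))
    rows = np.arange(n)
    X1[rows, be_idx] = 1.0
    X2[rows, e_idx] = 1.0
    Z[rows, g_idx] = 1.0
    return DesignSet(X1=X1, X2=X2, Z=Z, g_idx=g_idx, e_idx=e_idx, be_idx=be_idx)


@dataclass(frozen=True)
class GGEMatrix:
    """Environment-centered v×l matrix of cell means (the G+GE matrix)."""

    values: np.ndarray
    cell_counts: np.ndarray
    genotypes: list[str]
    environments: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.genotypes, columns=self.environments
        )


def center_gge_matrix(met: METTable) -> GGEMatrix:
    """Average each (genotype, environment) cell and center by environment.

    Centering by the environment mean only retains the genotype main effect in
    the matrix, so its SVD axes describe G+GE jointly.
    """
    counts = met.cell_counts().to_numpy()
    if (counts == 0).any():
        i, j = np.argwhere(counts == 0)[0]
        raise METValidationError(
            f"empty cell ({met.genotypes[i]}, {met.environments[j]}): the "
            "frequentist G+GE matrix needs every cell observed; fit the "
            "Bayesian model instead, which handles missing cells natively"
        )
    means = (
        met.records.groupby(["genotype", "environment"], observed=True)["response"]
        .mean()
        .unstack()
        .reindex(index=met.genotypes, columns=met.environments)
        .to_numpy()
    )
    centered = means - means.mean(axis=0, keepdims=True)
    return GGEMatrix(
        values=centered,
        cell_counts=counts,
        genotypes=list(met.genotypes),
        environments=list(met.environments),
    )


def svd_gge(m: GGEMatrix | np.ndarray, t: int | None = None):
    """Rank-t SVD of the G+GE matrix with a fixed sign convention.

    Returns ``(lam, A, Gamma)`` with ``lam`` nonincreasing, ``A`` (v×t) and
    ``Gamma`` (l×t) orthonormal-column matrices, and the sign of each axis
    chosen so the largest-magnitude element of the environment loading is
    positive.
    """
    values = m.values if isinstance(m, GGEMatrix) else np.asarray(m, dtype=float)
    v, l = values.shape
    if t is None:
        t = min(v - 1, l)
    U, s, Vt = np.linalg.svd(values, full_matrices=False)
    lam, A, Gamma = s[:t], U[:, :t], Vt[:t].T
    for k in range(t):
        j = np.argmax(np.abs(Gamma[:, k]))
        if Gamma[j, k] < 0:
            Gamma[:, k] = -Gamma[:, k]
            A[:, k] = -A[:, k]
    return lam, A, Gamma


def subset_environments(met: METTable, environments) -> METTable:
    """Restrict a MET table to an environment subset (mega-environment)."""
    keep = [str(e) for e in environments]
    unknown = sorted(set(keep) - set(met.environments))
    if unknown:
        raise METValidationError(f"unknown environment(s): {unknown}")
    sub = met.records[met.records["environment"].isin(keep)]
    if sub.empty:
        raise METValidationError("environment subset selects no records")
    return met_from_frame(sub)
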