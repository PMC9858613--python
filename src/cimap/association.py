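"""Association statistics on contingency tables.

Implements the information-theoretic machinery of the map-building
pipeline: plug-in mutual information (MI, bits), conditional MI as a
stratum-weighted average, the likelihood-ratio G-test (G = 2*N*ln2*MI, an
algebraic identity with plug-in MI), a stratified permutation test used
when expected counts are too sparse for the asymptotic chi-square
reference, and classical Pearson chi-square with phi / Cramer's V effect
sizes for the named follow-up comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import chi2_contingency

from .cohort import Cohort
from .errors import DegenerateTableError, DomainError, EmptyTableError, SchemaError

_LN2 = np.log(2.0)

# Relaxed Cochran-style sparsity rule: the asymptotic G-test is trusted only
# when >= 80% of expected counts (over non-empty margins) are >= 1 and all
# are >= 0.2; otherwise the permutation test is used.
COCHRAN_FRACTION = 0.8
COCHRAN_MIN_EXPECTED = 0.2
COCHRAN_BULK_EXPECTED = 1.0
DEFAULT_N_PERM = 9999


@dataclass
class ContingencyTable:
    """Counts over a cross-classification, optionally stratified.

    ``counts`` has shape (r, c) for a plain table or (s, r, c) when
    stratified; rows index ``row_variable`` levels, columns
    ``col_variable`` levels.
    """

    counts: np.ndarray
    row_variable: str
    col_variable: str
    row_levels: tuple
    col_levels: tuple
    strata_variables: tuple = ()
    n_excluded: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.min(initial=0) < 0:
            raise DomainError("counts must be non-negative")
        expect_ndim = 3 if self.strata_variables else 2
        if self.counts.ndim == 2 and expect_ndim == 3:
            raise SchemaError("stratified table requires 3-d counts")
        if self.counts.ndim not in (2, 3):
            raise SchemaError("counts must be 2-d or stratified 3-d")
        if self.counts.shape[-2] != len(self.row_levels) or self.counts.shape[
            -1
        ] != len(self.col_levels):
            raise SchemaError("counts shape does not match declared levels")

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def stratified(self) -> bool:
        return self.counts.ndim == 3

    def marginal(self) -> "ContingencyTable":
        """Collapse strata (no-op for a plain table)."""
        if not self.stratified:
            return self
        return ContingencyTable(
            self.counts.sum(axis=0),
            self.row_variable,
            self.col_variable,
            self.row_levels,
            self.col_levels,
            n_excluded=self.n_excluded,
        )

    def to_csv(self, path) -> None:
        if self.stratified:
            raise SchemaError("CSV export supports unstratified tables only")
        pd.DataFrame(
            self.counts, index=list(self.row_levels), columns=list(self.col_levels)
        ).to_csv(path, lineterminator="\n")

    @classmethod
    def from_csv(cls, path, row_variable="rows", col_variable="cols"):
        df = pd.read_csv(path, index_col=0)
        return cls(
            df.to_numpy(dtype=np.int64),
            row_variable,
            col_variable,
            tuple(str(i) for i in df.index),
            tuple(str(c) for c in df.columns),
        )


@dataclass
class AssociationResult:
    """Outcome of one association/independence test.

    ``mi`` is the plug-in (conditional) MI in bits; for the G-test it
    satisfies the identity g = 2 * N * ln(2) * mi exactly.
    """

    mi: float
    g: float
    df: int
    p: float
    n_effective: int
    method: str
    n_excluded: int = 0


@dataclass
class EffectSizeResult:
    """Pearson chi-square with phi (2x2) / Cramer's V effect sizes."""

    chi2: float
    df: int
    p: float
    phi: float | None
    cramers_v: float
    n: int


# ---------------------------------------------------------------------------
# code-level kernels (shared with the structure learner for speed)
# ---------------------------------------------------------------------------

def _counts_3d(xc, yc, zc, kx, ky, kz) -> np.ndarray:
    """Stratified counts (kz, kx, ky) from non-negative integer codes."""
    flat = (zc * kx + xc) * ky + yc
    return np.bincount(flat, minlength=kz * kx * ky).reshape(kz, kx, ky)


def _g_and_df(counts3d: np.ndarray) -> tuple:
    """Summed per-stratum G (natural log) and degrees of freedom.

    df counts, per non-empty stratum, (non-zero-margin rows - 1) times
    (non-zero-margin cols - 1).
    """
    g_total = 0.0
    df_total = 0
    for block in counts3d:
        nz = block.sum()
        if nz == 0:
            continue
        rm = block.sum(axis=1)
        cm = block.sum(axis=0)
        nnz_r = int((rm > 0).sum())
        nnz_c = int((cm > 0).sum())
        df_total += max(nnz_r - 1, 0) * max(nnz_c - 1, 0)
        expected = np.outer(rm, cm) / nz
        mask = block > 0
        g_total += 2.0 * float(
            (block[mask] * np.log(block[mask] / expected[mask])).sum()
        )
    return g_total, df_total


def _cmi_bits(counts3d: np.ndarray) -> float:
    g, _ = _g_and_df(counts3d)
    n = counts3d.sum()
    return g / (2.0 * n * _LN2) if n else 0.0


def _batched_cmi(tables: np.ndarray) -> np.ndarray:
    """CMI in bits for a batch of stratified tables, shape (B, s, r, c)."""
    t = tables.astype(float)
    nz = t.sum(axis=(2, 3))
    rm = t.sum(axis=3)
    cm = t.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = rm[..., :, None] * cm[..., None, :] / nz[..., None, None]
        terms = np.where(t > 0, t * np.log(np.where(t > 0, t, 1.0) / expected), 0.0)
    g = 2.0 * np.nansum(terms, axis=(1, 2, 3))
    n = t.sum(axis=(1, 2, 3))
    return g / (2.0 * np.maximum(n, 1.0) * _LN2)


def _sample_fixed_margin_tables(counts3d: np.ndarray, b: int, rng) -> np.ndarray:
    """Draw b tables from the permutation null (y shuffled within strata).

    Shuffling the y column within a stratum leaves the stratum's row and
    column margins fixed and makes every consistent table occur with the
    multivariate-hypergeometric probability, so the null is sampled
    directly cell-by-cell (vectorised over the batch) instead of shuffling
    record arrays. Returns an int array of shape (b, s, r, c).
    """
    kz, kx, ky = counts3d.shape
    out = np.zeros((b, kz, kx, ky), dtype=np.int64)
    for z in range(kz):
        block = counts3d[z].astype(np.int64)
        if block.sum() == 0:
            continue
        rm = block.sum(axis=1)
        cm = block.sum(axis=0)
        pool = np.broadcast_to(cm, (b, ky)).copy()  # unassigned column pool
        for i in range(kx):
            row_left = np.full(b, rm[i], dtype=np.int64)
            for j in range(ky):
                ngood = pool[:, j]
                # only columns not yet visited in this row can take the rest
                nbad = pool[:, j + 1:].sum(axis=1)
                take = np.where(
                    row_left > 0,
                    rng.hypergeometric(
                        np.maximum(ngood, 0), np.maximum(nbad, 0),
                        np.clip(row_left, 0, ngood + nbad),
                    ),
                    0,
                )
                out[:, z, i, j] = take
                pool[:, j] -= take
                row_left -= take
    return out


def _permutation_pvalue(counts3d: np.ndarray, n_perm: int, rng) -> float:
    """Permutation p-value for the stratum-weighted MI statistic."""
    obs = _cmi_bits(counts3d.astype(float))
    kz, kx, ky = counts3d.shape
    batch = max(1, int(2_000_000 / max(kz * kx * ky, 1)))
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        tables = _sample_fixed_margin_tables(counts3d, b, rng)
        stats = _batched_cmi(tables)
        exceed += int((stats >= obs - 1e-12).sum())
        done += b
    return (1.0 + exceed) / (1.0 + n_perm)


# ---------------------------------------------------------------------------
# cohort-level operations
# ---------------------------------------------------------------------------

def crosstab(
    cohort: Cohort, x: str, y: str, strata=None
) -> ContingencyTable:
    """Cross-classify two variables over pairwise-complete records.

    Records missing any involved variable (x, y or a stratifier) are
    excluded; the exclusion count is reported on the table.
    """
    if x == y:
        raise SchemaError("x and y must be distinct variables")
    strata = tuple(strata) if strata else ()
    names = [x, y, *strata]
    codes = cohort.codes(names)
    complete = (codes >= 0).all(axis=1)
    n_excluded = int((~complete).sum())
    codes = codes[complete]
    if codes.shape[0] == 0:
        raise EmptyTableError(
            f"no pairwise-complete records for ({x}, {y}) given {list(strata)}"
        )
    kx = cohort.dictionary[x].n_levels
    ky = cohort.dictionary[y].n_levels
    if strata:
        sizes = [cohort.dictionary[s].n_levels for s in strata]
        zc = np.zeros(codes.shape[0], dtype=np.int64)
        for j, size in enumerate(sizes):
            zc = zc * size + codes[:, 2 + j]
        kz = int(np.prod(sizes))
        counts = _counts_3d(codes[:, 0], codes[:, 1], zc, kx, ky, kz)
    else:
        counts = _counts_3d(
            codes[:, 0], codes[:, 1], np.zeros(codes.shape[0], dtype=np.int64),
            kx, ky, 1,
        )[0]
    return ContingencyTable(
        counts,
        x,
        y,
        cohort.dictionary[x].levels,
        cohort.dictionary[y].levels,
        strata_variables=strata,
        n_excluded=n_excluded,
    )


def mutual_information(table: ContingencyTable) -> float:
    """Plug-in MI in bits; for a stratified table, the stratum-weighted CMI."""
    if table.N == 0:
        raise EmptyTableError("mutual information undefined for an empty table")
    counts = table.counts if table.stratified else table.counts[None, ...]
    return _cmi_bits(counts.astype(float))


def entropy_bits(probabilities) -> float:
    """Shannon entropy in bits of a discrete distribution."""
    p = np.asarray(probabilities, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def conditional_mutual_information(cohort: Cohort, x: str, y: str, given) -> float:
    """CMI(x, y | given) in bits, the stratum-weighted plug-in MI.

    An empty conditioning set delegates to plain mutual information.
    """
    given = tuple(given) if given else ()
    return mutual_information(crosstab(cohort, x, y, strata=given or None))


def _cochran_ok(counts3d: np.ndarray) -> bool:
    expected = []
    for block in counts3d:
        nz = block.sum()
        if nz == 0:
            continue
        rm = block.sum(axis=1)
        cm = block.sum(axis=0)
        e = np.outer(rm, cm) / nz
        expected.append(e[np.outer(rm > 0, cm > 0)])
    if not expected:
        return False
    e = np.concatenate(expected)
    if e.size == 0:
        return False
    return (
        e.min() >= COCHRAN_MIN_EXPECTED
        and (e >= COCHRAN_BULK_EXPECTED).mean() >= COCHRAN_FRACTION
    )


def g_test(table: ContingencyTable, df_override: int | None = None) -> AssociationResult:
    """Likelihood-ratio G-test of (conditional) independence.

    G = 2 * sum O*ln(O/E) within each stratum (zero cells contribute 0),
    referred to a chi-square distribution. Degenerate tables (no usable
    degrees of freedom) raise :class:`DegenerateTableError`; callers fall
    back to the permutation test.
    """
    if table.N == 0:
        raise EmptyTableError("G-test undefined for an empty table")
    counts = table.counts if table.stratified else table.counts[None, ...]
    g, df = _g_and_df(counts.astype(float))
    if df_override is not None:
        df = df_override
    if df < 1:
        raise DegenerateTableError(
            f"table {table.row_variable} x {table.col_variable} has no usable "
            "degrees of freedom"
        )
    n = table.N
    return AssociationResult(
        mi=g / (2.0 * n * _LN2),
        g=g,
        df=df,
        p=float(chi2_dist.sf(g, df)),
        n_effective=n,
        method="g-test",
        n_excluded=table.n_excluded,
    )


def permutation_test(
    cohort: Cohort,
    x: str,
    y: str,
    given=None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> AssociationResult:
    """Permutation test of conditional independence.

    The observed statistic is the plug-in (conditional) MI; the null
    shuffles y within each conditioning stratum, sampled exactly via
    fixed-margin table resampling. p = (1 + #{permuted MI >= observed}) /
    (1 + n_perm). Deterministic for a fixed seed.
    """
    if n_perm < 99:
        raise DomainError("n_perm must be at least 99")
    given = tuple(given) if given else ()
    table = crosstab(cohort, x, y, strata=given or None)
    counts = table.counts if table.stratified else table.counts[None, ...]
    obs = _cmi_bits(counts.astype(float))
    rng = np.random.default_rng(seed)
    p = _permutation_pvalue(counts, n_perm, rng)
    n = table.N
    return AssociationResult(
        mi=obs,
        g=2.0 * n * _LN2 * obs,
        df=0,
        p=p,
        n_effective=n,
        method="permutation",
        n_excluded=table.n_excluded,
    )


def ci_test(
    cohort: Cohort,
    x: str,
    y: str,
    given=None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> AssociationResult:
    """Conditional-independence test with automatic method selection.

    Uses the asymptotic G-test when expected counts satisfy the relaxed
    Cochran rule, otherwise (or on a degenerate table) the stratified
    permutation test.
    """
    given = tuple(given) if given else ()
    table = crosstab(cohort, x, y, strata=given or None)
    counts = table.counts if table.stratified else table.counts[None, ...]
    if _cochran_ok(counts.astype(float)):
        try:
            return g_test(table)
        except DegenerateTableError:
            pass
    return permutation_test(cohort, x, y, given=given, n_perm=n_perm, seed=seed)


def chi_square_effect(table: ContingencyTable) -> EffectSizeResult:
    """Pearson chi-square (no continuity correction) with effect size.

    phi = sqrt(chi2/N) on 2x2 tables; Cramer's V = sqrt(chi2/(N*(min(r,c)-1)))
    in general (equal to phi on 2x2). Zero margins are an error naming the
    degenerate level.
    """
    if table.stratified:
        raise SchemaError("chi_square_effect expects an unstratified table")
    if table.N == 0:
        raise EmptyTableError("chi-square undefined for an empty table")
    counts = table.counts.astype(float)
    rm = counts.sum(axis=1)
    cm = counts.sum(axis=0)
    for margin, levels, which in ((rm, table.row_levels, table.row_variable),
                                  (cm, table.col_levels, table.col_variable)):
        if (margin == 0).any():
            level = levels[int(np.argmin(margin))]
            raise DegenerateTableError(
                f"zero margin for level {level!r} of {which!r}"
            )
    res = chi2_contingency(counts, correction=False)
    n = table.N
    r, c = counts.shape
    cramers_v = float(np.sqrt(res.statistic / (n * (min(r, c) - 1))))
    phi = float(np.sqrt(res.statistic / n)) if (r, c) == (2, 2) else None
    return EffectSizeResult(
        chi2=float(res.statistic),
        df=int(res.dof),
        p=float(res.pvalue),
        phi=phi,
        cramers_v=cramers_v,
        n=n,
    )
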