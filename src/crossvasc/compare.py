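"""Trajectory association testing and 30-bin cross-species conservation.

Per species, each gene's raw counts are regressed on a cubic B-spline basis
of pseudotime (negative-binomial GLM with a log library-size offset); a
likelihood-ratio test against the intercept-only model, BH-adjusted, flags
genes whose expression changes along the trajectory.  Each species'
trajectory is then divided into equal-cell pseudotime bins; for genes DE in
both species the binned mean expression profiles are compared by Pearson
correlation (one-sided test for positive association), and genes are
classified conserved / common-but-uncorrelated / species-specific / not DE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.interpolate import BSpline

from .config import ComparisonParams, GAMParams, log
from .datamodel import ContractError, ExpressionDataset
from .preprocess import bh_adjust
from .trajectory import PseudotimeAssignment

MIN_DE_CELLS = 50


def bspline_basis(t: np.ndarray, df: int = 6) -> np.ndarray:
    """Cubic B-spline basis with ``df`` columns, interior knots at
    pseudotime quantiles; the first basis function is dropped in favor of an
    explicit intercept in the regression."""
    t = np.asarray(t, dtype=float)
    lo, hi = t.min(), t.max()
    if hi <= lo:
        raise ContractError("pseudotime is constant; cannot build a spline basis")
    n_interior = df - 3
    interior = np.quantile(t, np.linspace(0, 1, n_interior + 2)[1:-1]) if n_interior > 0 else np.array([])
    knots = np.concatenate([[lo - 1e-9] * 4, interior, [hi + 1e-9] * 4])
    basis = BSpline.design_matrix(t, knots, 3).toarray()
    return basis[:, 1:]


@dataclass
class TrajectoryDEResult:
    """Per-gene association with a pseudotime trajectory in one species."""

    table: pd.DataFrame  # gene, lineage, species, lrt_stat, p_value, fdr, significant, status
    lineage: str
    species: str
    max_fdr: float

    def significant_genes(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "gene"])


def trajectory_de(
    dataset: ExpressionDataset,
    pseudotime: PseudotimeAssignment | pd.Series,
    params: GAMParams | None = None,
    lineage_name: str | None = None,
) -> TrajectoryDEResult:
    """NB spline regression of counts on pseudotime with an LRT per gene.

    The gene-wise dispersion is moment-estimated from a Poisson fit of the
    full model; full and intercept-only NB GLMs (log library-size offset)
    are compared by a chi-squared LRT with df equal to the basis dimension.
    Genes detected in fewer than ``min_expressed_fraction`` of lineage cells
    are reported NA; non-convergent fits are flagged and excluded from the
    BH universe.
    """
    params = params or GAMParams()
    pt = pseudotime.values if isinstance(pseudotime, PseudotimeAssignment) else pseudotime
    lineage_name = lineage_name or (
        pseudotime.lineage.name() if isinstance(pseudotime, PseudotimeAssignment) else "lineage"
    )
    cells = [c for c in dataset.cell_ids if c in pt.index]
    if len(cells) < MIN_DE_CELLS:
        raise ContractError(f"need at least {MIN_DE_CELLS} cells with pseudotime, got {len(cells)}")
    ds = dataset.subset_cells(cells)
    t = pt.reindex(cells).to_numpy(dtype=float)
    counts = np.asarray(ds.counts.todense())
    offset = np.log(counts.sum(axis=1))

    basis = bspline_basis(t, df=params.df)
    k = basis.shape[1]
    x_full = sm.add_constant(basis, has_constant="add")
    x_null = np.ones((len(t), 1))

    frac = (counts > 0).mean(axis=0)
    rows = []
    for gi, gene in enumerate(ds.gene_ids):
        y = counts[:, gi]
        if frac[gi] < params.min_expressed_fraction:
            rows.append({"gene": gene, "lrt_stat": np.nan, "p_value": np.nan, "status": "not_tested"})
            continue
        try:
            pois = sm.GLM(y, x_full, family=sm.families.Poisson(), offset=offset).fit(maxiter=100)
            mu = pois.fittedvalues
            alpha = float(np.sum((y - mu) ** 2 - mu) / max(np.sum(mu**2), 1e-12))
            alpha = float(np.clip(alpha, 1e-8, 100.0))
            fam = sm.families.NegativeBinomial(alpha=alpha)
            full = sm.GLM(y, x_full, family=fam, offset=offset).fit(maxiter=100)
            null = sm.GLM(y, x_null, family=fam, offset=offset).fit(maxiter=100)
            lrt = max(0.0, 2.0 * (full.llf - null.llf))
            if not np.isfinite(lrt):
                raise FloatingPointError("non-finite likelihood ratio")
            p = float(stats.chi2.sf(lrt, k))
        except Exception:
            rows.append({"gene": gene, "lrt_stat": np.nan, "p_value": np.nan, "status": "failed"})
            continue
        rows.append({"gene": gene, "lrt_stat": lrt, "p_value": p, "status": "tested"})

    table = pd.DataFrame(rows)
    table.insert(1, "lineage", lineage_name)
    table.insert(2, "species", ds.species)
    tested = table["status"] == "tested"
    fdr = np.full(len(table), np.nan)
    fdr[tested.to_numpy()] = bh_adjust(table.loc[tested, "p_value"].to_numpy())
    table["fdr"] = fdr
    table["significant"] = tested & (table["fdr"] <= params.max_fdr)
    n_failed = int((table["status"] == "failed").sum())
    log.info(
        "trajectory_de: %s/%s: %d genes tested, %d significant at FDR<=%g, %d skipped, %d failed",
        ds.species, lineage_name, int(tested.sum()), int(table["significant"].sum()),
        params.max_fdr, int((table["status"] == "not_tested").sum()), n_failed,
    )
    return TrajectoryDEResult(
        table=table, lineage=lineage_name, species=ds.species, max_fdr=params.max_fdr
    )


# ----------------------------------------------------------------------
# Binning
# ----------------------------------------------------------------------

def bin_pseudotime(pseudotime: PseudotimeAssignment | pd.Series, n_bins: int = 30) -> pd.Series:
    """Partition cells into n_bins contiguous equal-cell blocks of the
    pseudotime order (ties broken by cell id); when N mod n_bins = r > 0 the
    first r bins receive one extra cell."""
    pt = pseudotime.values if isinstance(pseudotime, PseudotimeAssignment) else pseudotime
    n = len(pt)
    if n < n_bins:
        raise ContractError(f"need at least n_bins={n_bins} cells, got {n}")
    order = sorted(zip(pt.to_numpy(), pt.index))
    base, extra = divmod(n, n_bins)
    bins = np.empty(n, dtype=int)
    pos = 0
    for b in range(n_bins):
        size = base + (1 if b < extra else 0)
        bins[pos: pos + size] = b
        pos += size
    cells = [c for _, c in order]
    return pd.Series(bins, index=pd.Index(cells, name="cell_id"), name="bin")


@dataclass
class BinProfiles:
    """Genes × bins matrix of mean normalized expression for one species'
    lineage, bins ordered by pseudotime."""

    values: pd.DataFrame  # index gene, columns 0..n_bins-1
    species: str = ""
    lineage: str = ""

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def bin_profile(
    dataset: ExpressionDataset, bins: pd.Series, lineage: str = ""
) -> BinProfiles:
    """Mean normalized expression of each gene in each pseudotime bin."""
    cells = [c for c in bins.index if c in set(dataset.cell_ids)]
    ds = dataset.subset_cells(cells)
    norm = ds.normalized_dense()
    b = bins.reindex(cells).to_numpy()
    n_bins = int(b.max()) + 1
    mat = np.zeros((ds.n_genes, n_bins))
    for bi in range(n_bins):
        mask = b == bi
        if mask.any():
            mat[:, bi] = norm[mask].mean(axis=0)
    values = pd.DataFrame(mat, index=pd.Index(ds.gene_ids, name="gene"), columns=range(n_bins))
    return BinProfiles(values=values, species=ds.species, lineage=lineage)


# ----------------------------------------------------------------------
# Cross-species correlation and classification
# ----------------------------------------------------------------------

def cross_species_correlation(
    profiles_a: BinProfiles,
    profiles_b: BinProfiles,
    genes: list[str],
    params: ComparisonParams | None = None,
) -> pd.DataFrame:
    """Per-gene Pearson correlation of binned profiles across species.

    One-sided p for positive correlation via the t-statistic with
    n_bins - 2 df (or, if configured, a circular-shift permutation test);
    BH across genes; pass requires r >= min_corr and fdr <= max_fdr.
    Zero-variance profiles give an NA row excluded from the BH universe.
    """
    params = params or ComparisonParams()
    if profiles_a.n_bins != profiles_b.n_bins:
        raise ContractError("profiles have different bin counts")
    n_bins = profiles_a.n_bins
    rows = []
    for gene in genes:
        if gene not in profiles_a.values.index or gene not in profiles_b.values.index:
            raise ContractError(f"gene {gene!r} missing from a profile matrix")
        a = profiles_a.values.loc[gene].to_numpy(dtype=float)
        b = profiles_b.values.loc[gene].to_numpy(dtype=float)
        if a.std() == 0 or b.std() == 0:
            rows.append({"gene": gene, "r": np.nan, "p_value": np.nan, "status": "zero_variance"})
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if params.permutation_p:
            shifts = [float(np.corrcoef(a, np.roll(b, s))[0, 1]) for s in range(1, n_bins)]
            p = (1 + sum(rs >= r for rs in shifts)) / n_bins
        else:
            rr = float(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))
            tstat = rr * np.sqrt((n_bins - 2) / (1.0 - rr * rr))
            p = float(stats.t.sf(tstat, n_bins - 2))
        rows.append({"gene": gene, "r": r, "p_value": p, "status": "tested"})
    result = pd.DataFrame(rows, columns=["gene", "r", "p_value", "status"])
    tested = (result["status"] == "tested").to_numpy()
    fdr = np.full(len(result), np.nan)
    fdr[tested] = bh_adjust(result.loc[tested, "p_value"].to_numpy())
    result["fdr"] = fdr
    result["pass"] = tested & (result["r"] >= params.min_corr) & (result["fdr"] <= params.max_fdr)
    return result


CATEGORIES = (
    "conserved",
    "common_not_correlated",
    "species_specific_A",
    "species_specific_B",
    "not_DE",
)


@dataclass
class ConservationCall:
    """Per-gene conservation verdicts plus genes lacking a homolog match."""

    calls: pd.DataFrame  # gene, category, r, corr_fdr, fdr_A, fdr_B
    unmatched_a: list[str] = field(default_factory=list)
    unmatched_b: list[str] = field(default_factory=list)


def classify_conservation(
    de_a: TrajectoryDEResult,
    de_b: TrajectoryDEResult,
    corr: pd.DataFrame,
) -> ConservationCall:
    """Combine the two species' trajectory DE calls with the correlation.

    Over genes present in both species' (homolog-translated) results:
    conserved = DE in both and correlation pass; common_not_correlated = DE
    in both, correlation fail or NA; species_specific = DE in one species
    only; not_DE otherwise.  Genes present in only one species' result (no
    confident homolog) are reported separately.
    """
    a = de_a.table.set_index("gene")
    b = de_b.table.set_index("gene")
    shared = [g for g in a.index if g in b.index]
    unmatched_a = [g for g in a.index if g not in b.index]
    unmatched_b = [g for g in b.index if g not in a.index]
    corr_idx = corr.set_index("gene") if len(corr) else pd.DataFrame()

    rows = []
    for gene in shared:
        de_in_a = bool(a.loc[gene, "significant"])
        de_in_b = bool(b.loc[gene, "significant"])
        r = corr_fdr = np.nan
        passed = False
        if len(corr_idx) and gene in corr_idx.index:
            r = corr_idx.loc[gene, "r"]
            corr_fdr = corr_idx.loc[gene, "fdr"]
            passed = bool(corr_idx.loc[gene, "pass"])
        if de_in_a and de_in_b:
            category = "conserved" if passed else "common_not_correlated"
        elif de_in_a:
            category = "species_specific_A"
        elif de_in_b:
            category = "species_specific_B"
        else:
            category = "not_DE"
        rows.append(
            {
                "gene": gene,
                "category": category,
                "r": r,
                "corr_fdr": corr_fdr,
                "fdr_A": a.loc[gene, "fdr"],
                "fdr_B": b.loc[gene, "fdr"],
            }
        )
    calls = pd.DataFrame(rows, columns=["gene", "category", "r", "corr_fdr", "fdr_A", "fdr_B"])
    counts = calls["category"].value_counts().to_dict() if len(calls) else {}
    log.info("classify_conservation: %s (unmatched: %d A, %d B)", counts, len(unmatched_a), len(unmatched_b))
    return ConservationCall(calls=calls, unmatched_a=unmatched_a, unmatched_b=unmatched_b)
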