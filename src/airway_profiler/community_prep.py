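"""Preparation and diversity analysis of 16S amplicon OTU tables.

Covers the standard hygiene steps for low-biomass airway samples —
read/prevalence filtering of OTUs, flagging of likely reagent contaminants
by their negative correlation with qPCR biomass, rarefaction to a common
depth — and the alpha/beta-diversity statistics used to characterise
dysbiosis: Shannon index, richness, Pielou evenness, Bray–Curtis
dissimilarity, principal-coordinates analysis and PERMANOVA.

The contaminant rule reflects the mechanics of low-biomass sequencing: a
reagent contaminant contributes a roughly constant absolute input per
sample, so its *relative* abundance falls as true biomass rises, producing
a negative Spearman correlation with the qPCR load.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.spatial.distance as ssd
import scipy.stats as sps
import skbio
from statsmodels.stats.multitest import multipletests

from .ko_profiles import DistanceMatrix

__all__ = [
    "OTUTable",
    "DiversityProfile",
    "PermanovaResult",
    "PCoAResult",
    "validate_metadata",
    "filter_low_count_otus",
    "flag_biomass_contaminants",
    "benjamini_hochberg",
    "rarefy",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "permanova",
]

SAMPLE_CLASSES = ("sample", "extraction_control", "scope_control", "pcr_negative")


@dataclass(frozen=True)
class OTUTable:
    """Samples x OTUs count table with optional taxonomy.

    ``counts`` is a non-negative integer DataFrame (rows = samples);
    ``taxonomy`` maps retained OTU ids to lineage strings (kingdom..genus
    columns) and may cover more OTUs than the table.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self):
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValueError("duplicate sample or OTU ids")
        arr = c.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.number) or (arr < 0).any()
                         or not np.allclose(arr, np.round(arr))):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", c.astype(np.int64))
        if self.taxonomy is not None:
            missing = set(c.columns) - set(self.taxonomy.index)
            if missing:
                raise ValueError(f"taxonomy missing for OTUs: {sorted(missing)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            bad = totals[totals == 0].index.tolist()
            raise ValueError(f"zero-sum sample(s): {bad[:5]}")
        return self.counts.div(totals, axis=0)

    def subset_otus(self, otus) -> "OTUTable":
        tax = self.taxonomy.loc[list(otus)] if self.taxonomy is not None else None
        return OTUTable(self.counts[list(otus)], tax)


@dataclass(frozen=True)
class DiversityProfile:
    """Per-sample alpha diversity: Shannon H (nats), richness S, evenness J."""

    table: pd.DataFrame  # columns: shannon, richness, evenness


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_perm: int
    factor: str = ""


@dataclass(frozen=True)
class PCoAResult:
    coordinates: pd.DataFrame          # samples x retained positive axes
    eigenvalues: np.ndarray            # all eigenvalues, decreasing
    proportion_explained: np.ndarray   # over positive eigenvalues


def validate_metadata(meta: pd.DataFrame, table: OTUTable | None = None) -> pd.DataFrame:
    """Basic schema checks on a sample metadata frame (indexed by sample)."""
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    if table is not None:
        missing = set(table.sample_ids) - set(meta.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)[:5]}")
    if "sample_class" in meta:
        bad = set(meta["sample_class"].dropna()) - set(SAMPLE_CLASSES)
        if bad:
            raise ValueError(f"unknown sample_class values: {sorted(bad)}")
    if "biomass" in meta:
        bm = pd.to_numeric(meta["biomass"], errors="raise")
        if (bm.dropna() <= 0).any():
            raise ValueError("biomass must be positive where present")
    return meta


# ---------------------------------------------------------------------------
# filtering

def filter_low_count_otus(
    t: OTUTable, min_total_reads: int = 20, min_prevalence_frac: float = 0.02
) -> tuple[OTUTable, pd.DataFrame]:
    """Remove rare OTUs.

    An OTU is removed when its total read count across all samples is
    below ``min_total_reads`` *or* it is present (count > 0) in fewer than
    ``min_prevalence_frac`` of samples.  Returns the filtered table and a
    per-removed-OTU log of which rule(s) fired.
    """
    if min_total_reads < 0 or min_prevalence_frac < 0:
        raise ValueError("thresholds must be non-negative")
    totals = t.counts.sum(axis=0)
    prev = (t.counts > 0).mean(axis=0)
    low_reads = totals < min_total_reads
    low_prev = prev < min_prevalence_frac
    drop = low_reads | low_prev
    log = pd.DataFrame({
        "total_reads": totals[drop],
        "prevalence": prev[drop],
        "failed_reads": low_reads[drop],
        "failed_prevalence": low_prev[drop],
    })
    kept = [o for o in t.otu_ids if not drop[o]]
    return t.subset_otus(kept), log


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def flag_biomass_contaminants(
    t: OTUTable,
    meta: pd.DataFrame,
    rho_threshold: float = 0.2,
    fdr: float = 0.05,
    direction: str = "negative",
) -> pd.DataFrame:
    """Flag OTUs whose relative abundance tracks biomass like a contaminant.

    Computes, per OTU, the Spearman correlation between per-sample relative
    abundance and qPCR biomass, adjusts p-values by Benjamini–Hochberg
    across OTUs, and flags OTUs with adjusted p < ``fdr`` and
    |rho| > ``rho_threshold`` on the contaminant (negative) side, or on
    either side with ``direction="both"``.
    """
    if direction not in ("negative", "both"):
        raise ValueError("direction must be 'negative' or 'both'")
    if "biomass" not in meta:
        raise ValueError("metadata has no 'biomass' column")
    biomass = pd.to_numeric(meta.loc[t.sample_ids, "biomass"])
    ok = biomass.notna()
    if ok.sum() < 10:
        raise ValueError("need biomass for at least 10 samples")
    if biomass[ok].nunique() == 1:
        raise ValueError("biomass is constant; correlation undefined")
    rel = OTUTable(t.counts.loc[ok[ok].index]).relative_abundance()
    bm = biomass[ok].to_numpy()
    rho = np.empty(len(t.otu_ids))
    pval = np.empty(len(t.otu_ids))
    for j, otu in enumerate(t.otu_ids):
        r, p = sps.spearmanr(rel[otu].to_numpy(), bm)
        rho[j], pval[j] = (r, p) if np.isfinite(r) else (0.0, 1.0)
    p_adj = benjamini_hochberg(pval)
    if direction == "negative":
        hit = (rho <= -rho_threshold)
    else:
        hit = np.abs(rho) >= rho_threshold
    out = pd.DataFrame({
        "otu_id": t.otu_ids, "rho": rho, "p": pval, "p_adj": p_adj,
        "flagged": hit & (p_adj < fdr),
    }).set_index("otu_id")
    return out


# ---------------------------------------------------------------------------
# rarefaction and diversity

def rarefy(
    t: OTUTable,
    depth: int | str = "min",
    seed: int = 0,
    min_sample_reads: int = 1000,
) -> OTUTable:
    """Subsample every sample without replacement to a common depth.

    Samples with fewer than ``min_sample_reads`` total reads are discarded
    first; ``depth="min"`` then uses the smallest retained total.  Each
    sample is drawn once from the multivariate hypergeometric distribution,
    so the result is an integer table with identical row sums, reproducible
    for a fixed ``seed``.
    """
    totals = t.counts.sum(axis=1)
    kept = totals[totals >= min_sample_reads].index
    if len(kept) == 0:
        raise ValueError("no sample passes min_sample_reads")
    sub = t.counts.loc[kept]
    use_depth = int(sub.sum(axis=1).min()) if depth == "min" else int(depth)
    if use_depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    if (sub.sum(axis=1) < use_depth).any():
        raise ValueError("depth exceeds a retained sample's total")
    rng = np.random.default_rng(seed)
    out = np.vstack([
        rng.multivariate_hypergeometric(row, use_depth, method="marginals")
        for row in sub.to_numpy()
    ])
    return OTUTable(pd.DataFrame(out, index=sub.index, columns=sub.columns), t.taxonomy)


def alpha_diversity(t: OTUTable, base: float | None = None) -> DiversityProfile:
    """Shannon index (natural log by default), richness and Pielou evenness.

    Evenness J = H / ln(S) is undefined (NaN) for samples with a single
    OTU.  All-zero samples are rejected.
    """
    rel = t.relative_abundance().to_numpy()
    logf = np.log if base is None else (lambda x: np.log(x) / np.log(base))
    H = np.array([-(p[p > 0] * logf(p[p > 0])).sum() for p in rel])
    S = (rel > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        J = np.where(S > 1, H / logf(S.astype(float)), np.nan)
    df = pd.DataFrame({"shannon": H, "richness": S, "evenness": J}, index=t.sample_ids)
    return DiversityProfile(df)


def bray_curtis(t: OTUTable, transform: str = "relative") -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity between samples.

    ``transform="relative"`` (default) converts counts to relative
    abundances first; ``"none"`` uses raw counts.  Note Bray–Curtis is a
    dissimilarity, not a metric: the triangle inequality can fail.
    """
    if len(t.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    if transform not in ("relative", "none"):
        raise ValueError("transform must be 'relative' or 'none'")
    x = t.relative_abundance() if transform == "relative" else t.counts
    if transform == "none" and (t.counts.sum(axis=1) == 0).any():
        raise ValueError("zero-sum sample")
    d = ssd.squareform(ssd.pdist(x.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix(t.sample_ids, d)


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> PCoAResult:
    """Classical metric scaling of a distance matrix.

    Eigenvalues of the double-centred -D^2/2 matrix are reported in full;
    coordinates are returned for positive eigenvalues only (negative
    eigenvalues, which arise for non-Euclidean dissimilarities such as
    Bray–Curtis, carry no real coordinates).
    """
    res = skbio.stats.ordination.pcoa(
        skbio.DistanceMatrix(d.d, ids=d.ids), method="eigh",
    )
    eig = res.eigvals.to_numpy()
    pos = eig > 1e-10 * max(eig.max(), 1.0)
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        import warnings

        warnings.warn(f"only {n_pos} positive axes available; truncating")
        n_axes = n_pos
    coords = res.samples.iloc[:, :n_axes]
    coords.index = d.ids
    prop = eig[pos] / eig[pos].sum() if n_pos else np.array([])
    return PCoAResult(coords, eig, prop)


def _permanova_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(groups)
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    d: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0, factor: str = ""
) -> PermanovaResult:
    """Permutational multivariate analysis of variance on a distance matrix.

    The pseudo-F statistic compares among-group to within-group sums of
    squared distances; significance is assessed by permuting group labels,
    with p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) so p is never 0.
    """
    labels = np.asarray(pd.Series(groups).loc[d.ids] if isinstance(groups, pd.Series) else groups)
    if len(labels) != d.n:
        raise ValueError("group labels do not match distance matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    d2 = d.d ** 2
    f_obs = _permanova_f(d2, labels, uniq)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _permanova_f(d2, perm, uniq) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(p), n_perm, factor)
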