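"""Sperm methylome analysis from per-sample CpG count tables.

The analysis takes bisulfite-sequencing count tables (methylated / total
reads per CpG per sample), filters sites by detection and coverage, tests
Addict-vs-Non-addict differential methylation within each generation by a
pooled-count two-sided Fisher exact test with Benjamini–Hochberg FDR
control, and intersects the per-generation calls into the set of
"maintained differences": CpGs significant in both F0 and F1 with the same
direction of change.  Downstream summaries — genomic-element annotation,
hypomethylation flags, enrichment odds ratios, metagene profiles and
classical MDS — characterise that maintained set.

Sites are held 0-based internally; coordinate conversion happens once at the
I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as tstats
from .errors import ConfigurationError, DomainError, FormatError

logger = logging.getLogger(__name__)

GENERATIONS = ("F0", "F1")
PHENOTYPES = ("Saline", "Addict", "Non-addict")


# ---------------------------------------------------------------------------
# containers


@dataclass
class MethylMatrix:
    """CpG sites x samples count matrix with per-sample metadata.

    sites: DataFrame with columns (chrom, pos), 0-based, sorted.
    meth/total: integer arrays of shape (n_sites, n_samples).
    samples: DataFrame with columns (sample_id, generation, phenotype).
    """

    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self):
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        ns, nsamp = len(self.sites), len(self.samples)
        if self.meth.shape != (ns, nsamp) or self.total.shape != (ns, nsamp):
            raise FormatError("count matrices must be (n_sites, n_samples)")
        if (self.meth < 0).any() or (self.total < 0).any():
            raise FormatError("negative read counts")
        if (self.meth > self.total).any():
            raise FormatError("methylated count exceeds total coverage")
        if self.samples["sample_id"].duplicated().any():
            raise FormatError("sample ids must be unique")
        key = list(zip(self.sites["chrom"], self.sites["pos"]))
        if key != sorted(key):
            raise FormatError("sites must be sorted by (chrom, pos)")
        if len(set(key)) != len(key):
            raise FormatError("duplicate sites")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> pd.Series:
        return self.sites["chrom"].astype(str) + ":" + self.sites["pos"].astype(str)

    def levels(self) -> np.ndarray:
        """Per-site, per-sample methylation fraction; NaN where uncovered."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.meth / np.maximum(self.total, 1), np.nan)

    def sample_mask(self, generation: str | None = None, phenotype: str | None = None) -> np.ndarray:
        mask = np.ones(len(self.samples), dtype=bool)
        if generation is not None:
            mask &= (self.samples["generation"] == generation).to_numpy()
        if phenotype is not None:
            mask &= (self.samples["phenotype"] == phenotype).to_numpy()
        return mask

    def subset_sites(self, keep: np.ndarray) -> "MethylMatrix":
        return MethylMatrix(
            self.sites.loc[keep].reset_index(drop=True),
            self.meth[keep],
            self.total[keep],
            self.samples.copy(),
        )


@dataclass(frozen=True)
class FilterConfig:
    """Site-detection filter: kept sites are covered >= min_coverage reads in
    at least min_samples_detected samples (default: more than 6 of 16, >=5x)."""

    min_samples_detected: int = 7
    min_coverage: int = 5

    def __post_init__(self):
        if self.min_samples_detected < 1 or self.min_coverage < 1:
            raise ConfigurationError("filter thresholds must be >= 1")


@dataclass
class GeneModel:
    """Gene records with strand-aware TSS/TES and exon blocks.

    genes: DataFrame with columns gene_id, chrom, strand (+/-), start, end
    (0-based half-open gene span) and exon_starts/exon_ends (lists of ints).
    For a minus-strand gene the TSS is the last base of the span (end-1).
    """

    genes: pd.DataFrame

    def __post_init__(self):
        required = {"gene_id", "chrom", "strand", "start", "end", "exon_starts", "exon_ends"}
        missing = required - set(self.genes.columns)
        if missing:
            raise FormatError(f"gene model missing columns: {sorted(missing)}")
        if not self.genes["strand"].isin(["+", "-"]).all():
            raise FormatError("strand must be '+' or '-'")
        self.genes = self.genes.reset_index(drop=True)

    def __len__(self):
        return len(self.genes)

    @property
    def tss(self) -> np.ndarray:
        plus = self.genes["strand"].to_numpy() == "+"
        return np.where(plus, self.genes["start"].to_numpy(), self.genes["end"].to_numpy() - 1)

    @property
    def tes(self) -> np.ndarray:
        plus = self.genes["strand"].to_numpy() == "+"
        return np.where(plus, self.genes["end"].to_numpy() - 1, self.genes["start"].to_numpy())


@dataclass
class EnrichmentResult:
    table: tuple  # (a, b, c, d)
    odds_ratio: float
    ci95: tuple
    fisher_p: float

    def to_dict(self) -> dict:
        return {
            "table": list(self.table),
            "odds_ratio": self.odds_ratio,
            "ci95": list(self.ci95),
            "fisher_p": self.fisher_p,
        }


# ---------------------------------------------------------------------------
# filtering and differential methylation


def filter_sites(m: MethylMatrix, cfg: FilterConfig | None = None) -> MethylMatrix:
    """Keep sites detected at >= min_coverage in >= min_samples_detected samples."""
    cfg = cfg or FilterConfig()
    detected = (m.total >= cfg.min_coverage).sum(axis=1)
    return m.subset_sites(detected >= cfg.min_samples_detected)


def dmc_test(
    m: MethylMatrix,
    generation: str,
    alpha: float = 0.05,
    use_fdr: bool = True,
) -> pd.DataFrame:
    """Per-CpG Addict-vs-Non-addict differential methylation within a generation.

    Read counts are pooled across samples within each phenotype group; each
    site is tested with a two-sided Fisher exact test on the 2x2 table
    (methylated/unmethylated x Addict/Non-addict), and p-values are BH
    adjusted across tested sites.  Sites with zero pooled coverage in either
    group are excluded and counted in the returned table's
    ``attrs["n_skipped"]``.  A warning is logged when between-sample level
    variance exceeds 3x the binomial expectation (the pooled test assumes
    no extra-binomial variation).
    """
    if generation not in GENERATIONS:
        raise DomainError(f"unknown generation {generation!r}")
    mask_a = m.sample_mask(generation, "Addict")
    mask_n = m.sample_mask(generation, "Non-addict")
    if not mask_a.any() or not mask_n.any():
        raise DomainError(f"both phenotype groups required in generation {generation}")

    meth_a = m.meth[:, mask_a].sum(axis=1)
    tot_a = m.total[:, mask_a].sum(axis=1)
    meth_n = m.meth[:, mask_n].sum(axis=1)
    tot_n = m.total[:, mask_n].sum(axis=1)

    testable = (tot_a > 0) & (tot_n > 0)
    n_skipped = int((~testable).sum())
    if n_skipped:
        logger.info("dmc_test %s: skipped %d sites with empty pooled group", generation, n_skipped)

    _overdispersion_check(m, mask_a | mask_n, generation)

    a, ta = meth_a[testable], tot_a[testable]
    n, tn = meth_n[testable], tot_n[testable]
    level_a = a / ta
    level_n = n / tn
    diff = level_a - level_n
    p = tstats.fisher_exact_vec(a, ta - a, n, tn - n)
    q = tstats.bh_adjust(p)
    sig = (q if use_fdr else p) <= alpha

    out = pd.DataFrame(
        {
            "chrom": m.sites.loc[testable, "chrom"].to_numpy(),
            "pos": m.sites.loc[testable, "pos"].to_numpy(),
            "level_A": level_a,
            "level_N": level_n,
            "diff": diff,
            "p": p,
            "q": q,
            "direction": np.sign(diff).astype(int),
            "significant": sig,
        }
    )
    out.attrs["n_skipped"] = n_skipped
    out.attrs["generation"] = generation
    return out


def _overdispersion_check(m: MethylMatrix, mask: np.ndarray, label: str) -> None:
    lv = m.levels()[:, mask]
    tot = m.total[:, mask]
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = np.nanmean(lv, axis=1)
        obs_var = np.nanvar(lv, axis=1)
        exp_var = np.nanmean(
            np.where(tot > 0, pbar[:, None] * (1 - pbar[:, None]) / np.maximum(tot, 1), np.nan),
            axis=1,
        )
    ok = np.isfinite(obs_var) & np.isfinite(exp_var) & (exp_var > 0)
    if ok.any():
        ratio = np.median(obs_var[ok] / exp_var[ok])
        if ratio > 3.0:
            logger.warning(
                "dmc_test %s: median between-sample variance %.1fx binomial expectation; "
                "pooled counts may overstate significance",
                label,
                ratio,
            )


def maintained_differences(f0: pd.DataFrame, f1: pd.DataFrame) -> pd.DataFrame:
    """CpGs significant in both generations with the same direction of change."""
    key = ["chrom", "pos"]
    s0 = f0[f0["significant"]][key + ["direction", "diff"]]
    s1 = f1[f1["significant"]][key + ["direction", "diff"]]
    merged = s0.merge(s1, on=key, suffixes=("_f0", "_f1"))
    kept = merged[merged["direction_f0"] == merged["direction_f1"]]
    return kept.reset_index(drop=True)


# ---------------------------------------------------------------------------
# annotation and enrichment


def annotate_sites(sites: pd.DataFrame, gm: GeneModel, window: int = 2000) -> pd.DataFrame:
    """Assign each site to {promoter, exon, intron, intergenic} (+ gene id).

    Precedence promoter > exon > intron > intergenic.  A promoter is the
    closed window [TSS−window, TSS+window] around the strand-aware TSS; a
    site in several promoters resolves to the gene with the nearest TSS.
    Sites on chromosomes absent from the gene model are intergenic (with a
    warning logged once).
    """
    element = np.full(len(sites), "intergenic", dtype=object)
    gene_id = np.full(len(sites), "", dtype=object)
    if len(gm) == 0:
        return pd.DataFrame({"element": element, "gene_id": gene_id}, index=sites.index)

    genes = gm.genes
    tss_all = gm.tss
    unknown = set()
    row_of = {lab: i for i, lab in enumerate(sites.index)}
    for chrom, idx in sites.groupby("chrom", sort=False).groups.items():
        gsel = np.flatnonzero(genes["chrom"].to_numpy() == chrom)
        pos = sites.loc[idx, "pos"].to_numpy()
        rows = [row_of[lab] for lab in idx]
        if gsel.size == 0:
            unknown.add(chrom)
            continue
        tss = tss_all[gsel]
        dist = np.abs(pos[:, None] - tss[None, :])  # sites x genes on this chrom
        nearest = np.argmin(dist, axis=1)
        nearest_dist = dist[np.arange(len(pos)), nearest]
        is_prom = nearest_dist <= window

        gstart = genes["start"].to_numpy()[gsel]
        gend = genes["end"].to_numpy()[gsel]
        in_gene = (pos[:, None] >= gstart[None, :]) & (pos[:, None] < gend[None, :])
        in_exon = np.zeros_like(in_gene)
        for j, g in enumerate(gsel):
            es = np.asarray(genes.at[g, "exon_starts"])
            ee = np.asarray(genes.at[g, "exon_ends"])
            if es.size:
                in_exon[:, j] = ((pos[:, None] >= es[None, :]) & (pos[:, None] < ee[None, :])).any(axis=1)

        for k in range(len(pos)):
            r = rows[k]
            if is_prom[k]:
                element[r] = "promoter"
                gene_id[r] = genes.at[gsel[nearest[k]], "gene_id"]
            elif in_exon[k].any():
                j = int(np.flatnonzero(in_exon[k])[np.argmin(dist[k, in_exon[k]])])
                element[r] = "exon"
                gene_id[r] = genes.at[gsel[j], "gene_id"]
            elif in_gene[k].any():
                j = int(np.flatnonzero(in_gene[k])[np.argmin(dist[k, in_gene[k]])])
                element[r] = "intron"
                gene_id[r] = genes.at[gsel[j], "gene_id"]
    if unknown:
        logger.warning("annotate_sites: chromosomes absent from gene model: %s", sorted(unknown))
    return pd.DataFrame({"element": element, "gene_id": gene_id}, index=sites.index)


def hypo_flags(m: MethylMatrix, threshold: float = 0.3) -> pd.Series:
    """True where the maximum per-sample methylation fraction is <= threshold.

    Sites with no covered sample get NaN (undefined; excluded from
    enrichment denominators).
    """
    lv = m.levels()
    covered = np.isfinite(lv).any(axis=1)
    with np.errstate(invalid="ignore"):
        mx = np.nanmax(np.where(np.isfinite(lv), lv, -np.inf), axis=1)
    out = pd.Series(np.where(covered, mx <= threshold + 1e-12, np.nan), index=m.sites.index)
    return out


def enrichment(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """Odds ratio with 95% Wald CI and Fisher p for a 2x2 count table.

    The table is [[a, b], [c, d]]; when any cell is zero the
    Haldane–Anscombe +0.5 correction is applied to the OR and its CI.
    """
    cells = np.array([a, b, c, d], dtype=np.float64)
    if (cells < 0).any():
        raise DomainError("counts must be non-negative")
    if cells.sum() == 0:
        raise DomainError("all-zero 2x2 table")
    p = tstats.fisher_exact_two_sided(int(a), int(b), int(c), int(d))
    if (cells == 0).any():
        cells = cells + 0.5
    aa, bb, cc, dd = cells
    orr = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo, hi = np.exp(np.log(orr) - 1.96 * se), np.exp(np.log(orr) + 1.96 * se)
    return EnrichmentResult((int(a), int(b), int(c), int(d)), float(orr), (float(lo), float(hi)), p)


def feature_enrichment(
    target_flags: pd.Series | np.ndarray, background_flags: pd.Series | np.ndarray
) -> EnrichmentResult:
    """Enrichment of a boolean feature in a target site set vs its background.

    Builds the 2x2 (feature+/feature− x target/background) and delegates to
    :func:`enrichment`.  NaN flags (undefined feature) are dropped.
    """
    t = pd.Series(target_flags).dropna().astype(bool)
    bg = pd.Series(background_flags).dropna().astype(bool)
    return enrichment(int(t.sum()), int((~t).sum()), int(bg.sum()), int((~bg).sum()))


# ---------------------------------------------------------------------------
# profiles and ordination


def metagene_profile(
    m: MethylMatrix,
    gm: GeneModel,
    n_bins: int = 20,
    flank: int = 2000,
) -> pd.DataFrame:
    """Mean methylation over upstream / gene-body / downstream zones per group.

    Gene bodies are scaled to [0, 1] and cut into n_bins; the flanks are
    fixed-width (flank bp) with n_bins each.  Minus-strand genes are
    reversed so "upstream" always means 5'.  Per sample group
    (phenotype-generation), each bin reports the unweighted mean of pooled
    site-level methylation over all (site, gene) assignments; empty bins are
    NaN, never zero.  Genes shorter than n_bins bases are skipped.
    """
    if len(gm) == 0:
        raise DomainError("metagene profile needs at least one gene")
    if n_bins < 1:
        raise DomainError("n_bins must be >= 1")

    groups = (m.samples["phenotype"] + "-" + m.samples["generation"]).to_numpy()
    labels = list(dict.fromkeys(groups))
    pooled = {}
    for lab in labels:
        mask = groups == lab
        tm = m.meth[:, mask].sum(axis=1)
        tt = m.total[:, mask].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pooled[lab] = np.where(tt > 0, tm / np.maximum(tt, 1), np.nan)

    # accumulate (zone, bin) -> sums per group
    zones = ("upstream", "body", "downstream")
    sums = {lab: np.zeros((3, n_bins)) for lab in labels}
    counts = {lab: np.zeros((3, n_bins), dtype=np.int64) for lab in labels}
    n_skipped = 0

    chrom_arr = m.sites["chrom"].to_numpy()
    pos_arr = m.sites["pos"].to_numpy()
    for g in gm.genes.itertuples():
        length = g.end - g.start
        if length < n_bins:
            n_skipped += 1
            continue
        tss = g.start if g.strand == "+" else g.end - 1
        tes = g.end - 1 if g.strand == "+" else g.start
        on_chrom = chrom_arr == g.chrom
        pos = pos_arr[on_chrom]
        sel = np.flatnonzero(on_chrom)
        lo = min(g.start, tss - flank, tes - flank)
        hi = max(g.end, tss + flank, tes + flank)
        near = (pos >= lo) & (pos <= hi)
        for si, p in zip(sel[near], pos[near]):
            if g.strand == "+":
                rel_up = p - tss
                inside = g.start <= p < g.end
                rel_body = (p - g.start) / length
                rel_down = p - tes
            else:
                rel_up = tss - p
                inside = g.start <= p < g.end
                rel_body = (g.end - 1 - p) / length
                rel_down = tes - p
            if inside:
                zone, b = 1, min(int(rel_body * n_bins), n_bins - 1)
            elif -flank <= rel_up < 0:
                zone, b = 0, min(int((rel_up + flank) / flank * n_bins), n_bins - 1)
            elif 0 < rel_down <= flank:
                zone, b = 2, min(int((rel_down - 1) / flank * n_bins), n_bins - 1)
            else:
                continue
            for lab in labels:
                v = pooled[lab][si]
                if np.isfinite(v):
                    sums[lab][zone, b] += v
                    counts[lab][zone, b] += 1
    if n_skipped:
        logger.info("metagene_profile: skipped %d genes shorter than %d bp", n_skipped, n_bins)

    rows = []
    for zi, zone in enumerate(zones):
        for b in range(n_bins):
            row = {"zone": zone, "bin": b}
            for lab in labels:
                c = counts[lab][zi, b]
                row[lab] = sums[lab][zi, b] / c if c else np.nan
                row[f"n_{lab}"] = int(c)
            rows.append(row)
    return pd.DataFrame(rows)


def mds_embedding(m: MethylMatrix, dims: int = 2, impute: bool = False) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples on Euclidean methylation distances.

    Uses methylation fractions at complete-case sites (covered in every
    sample) by default, or site-mean imputation when ``impute=True``.
    Coordinates are centred at the origin; for a reproducible orientation
    the first nonzero loading of each dimension is made positive.
    """
    nsamp = len(m.samples)
    if nsamp < dims + 1:
        raise DomainError(f"need at least {dims + 1} samples for {dims}-D MDS")
    lv = m.levels()
    complete = np.isfinite(lv).all(axis=1)
    if impute:
        x = lv.copy()
        mu = np.nanmean(x, axis=1)
        any_cov = np.isfinite(x).any(axis=1)
        x = x[any_cov]
        mu = mu[any_cov]
        ind = np.where(np.isfinite(x), x, mu[:, None])
        x = ind
    else:
        x = lv[complete]
    if x.shape[0] < dims:
        raise DomainError(
            f"only {x.shape[0]} usable sites; need >= {dims} (consider impute=True)"
        )
    d2 = ((x[:, :, None] - x[:, None, :]) ** 2).sum(axis=0)  # squared distances
    j = np.eye(nsamp) - np.ones((nsamp, nsamp)) / nsamp
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[order], 0, None)
    coords = evecs[:, order] * np.sqrt(lam)[None, :]
    for k in range(dims):
        col = coords[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    out = pd.DataFrame(coords, columns=[f"dim{k+1}" for k in range(dims)])
    out.insert(0, "sample_id", m.samples["sample_id"].to_numpy())
    out["generation"] = m.samples["generation"].to_numpy()
    out["phenotype"] = m.samples["phenotype"].to_numpy()
    return out
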