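"""Synthetic cohorts with planted ground truth.

Two generators mirror the study design so every analysis stage can be
verified against known truth:

* an operant-behaviour cohort — each rat carries a latent "motivation"
  scalar that raises both its FR5 pressing (negative-binomial counts) and
  its progressive-ratio capacity, so the combined-score classifier should
  recover high-motivation animals as Addict;
* an RRBS-like methylation experiment — 16 sperm samples in 5 groups
  (Saline/Addict/Non-addict F0, Addict/Non-addict F1), bimodal per-CpG
  baseline methylation, negative-binomial coverage, beta-binomial
  methylated counts, a global demethylation shift in the cocaine-exposed F0
  groups, and a planted set of Addict-vs-Non-addict differential CpGs of
  which a fraction is maintained into F1.

Randomness follows a single master seed; each generator and each stage
within it draws from a named, independently derived substream, so e.g.
adding CpG sites never perturbs the behaviour draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .behavior import PRSchedule, pr_requirement
from .errors import ConfigurationError
from .methylome import GeneModel, MethylMatrix

METHYL_GROUPS = ("Saline-F0", "Addict-F0", "Non-addict-F0", "Addict-F1", "Non-addict-F1")

# named substreams off the master seed (see rng_for)
_SUBSTREAMS = {
    "behavior": 0,
    "methylome-baseline": 1,
    "methylome-planted": 2,
    "methylome-counts": 3,
    "methylome-positions": 4,
    "gene-model": 5,
    "de-table": 6,
}


def rng_for(master_seed: int, name: str) -> np.random.Generator:
    """Generator for a named substream of the master seed."""
    if name not in _SUBSTREAMS:
        raise ConfigurationError(f"unknown substream {name!r}")
    ss = np.random.SeedSequence(master_seed, spawn_key=(_SUBSTREAMS[name],))
    return np.random.default_rng(ss)


def _nb_draw(rng: np.random.Generator, mean, dispersion, size=None):
    """Negative binomial with mean/dispersion parameterisation (var = m + m^2/k)."""
    mean = np.asarray(mean, dtype=np.float64)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size if size is not None else mean.shape)


# ---------------------------------------------------------------------------
# behaviour


@dataclass(frozen=True)
class BehaviorSimConfig:
    """Operant-cohort generator settings.

    The latent motivation m_i ~ Normal(0, motivation_sd) acts on the log
    scale: FR5 session presses are NB with mean
    base_fr5_mean * exp(motivation_effect_fr5 * m_i), and the PR capacity is
    bp_capacity_base * exp(motivation_effect_bp * m_i) presses.
    """

    n_animals: int = 134
    base_fr5_mean: float = 150.0
    fr5_dispersion: float = 8.0
    motivation_sd: float = 0.4
    motivation_effect_fr5: float = 0.5
    motivation_effect_bp: float = 0.5
    bp_capacity_base: float = 60.0
    n_fr1: int = 5
    n_fr3: int = 2
    n_fr5: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals < 3:
            raise ConfigurationError("n_animals must be >= 3 (z-scores undefined below)")
        for name in ("base_fr5_mean", "fr5_dispersion", "bp_capacity_base"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.motivation_sd < 0:
            raise ConfigurationError("motivation_sd must be >= 0")
        for name in ("n_fr1", "n_fr3", "n_fr5"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


def simulate_behavior_cohort(
    cfg: BehaviorSimConfig, sched: PRSchedule | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate session logs for a cohort; returns (sessions, latent).

    sessions has one row per animal-session over FR1/FR3/FR5 training and a
    final PR session; latent holds each animal's motivation scalar and PR
    capacity.  The PR session earns injections while the press requirement
    stays within the animal's capacity; the break point is the requirement
    of the last injection earned (the >1 h-to-requirement stopping rule of
    a real chamber is emulated by the capacity cutoff).
    """
    cfg.validate()
    sched = sched or PRSchedule()
    rng = rng_for(cfg.seed, "behavior")
    n = cfg.n_animals
    ids = [f"R{i:04d}" for i in range(n)]
    motivation = rng.normal(0.0, cfg.motivation_sd, size=n) if cfg.motivation_sd > 0 else np.zeros(n)

    fr5_mu = cfg.base_fr5_mean * np.exp(cfg.motivation_effect_fr5 * motivation)
    capacity = cfg.bp_capacity_base * np.exp(cfg.motivation_effect_bp * motivation)

    rows = []
    for i, aid in enumerate(ids):
        s = 0
        for schedule, ratio, n_sessions in (
            ("FR1", 1, cfg.n_fr1),
            ("FR3", 3, cfg.n_fr3),
            ("FR5", 5, cfg.n_fr5),
        ):
            mu = fr5_mu[i] * ratio / 5.0
            for _ in range(n_sessions):
                active = int(_nb_draw(rng, np.float64(mu), cfg.fr5_dispersion, size=()))
                inactive = int(rng.poisson(5))
                rows.append((aid, s, schedule, active, inactive, active // ratio, np.nan))
                s += 1
        # PR ladder against capacity
        k = 0
        presses = 0
        while pr_requirement(k + 1, sched) <= capacity[i]:
            k += 1
            presses += pr_requirement(k, sched)
        bp = pr_requirement(k, sched) if k > 0 else 0
        inactive = int(rng.poisson(5))
        rows.append((aid, s, "PR", presses, inactive, k, float(bp)))

    sessions = pd.DataFrame(
        rows,
        columns=[
            "animal_id",
            "session_index",
            "schedule",
            "active_presses",
            "inactive_presses",
            "injections",
            "break_point",
        ],
    )
    latent = pd.DataFrame(
        {"animal_id": ids, "motivation": motivation, "fr5_mu": fr5_mu, "pr_capacity": capacity}
    )
    return sessions, latent


# ---------------------------------------------------------------------------
# methylome


@dataclass(frozen=True)
class MethylSimConfig:
    """RRBS-like count-matrix generator settings.

    Baseline per-CpG methylation is a two-component Beta mixture (weight_hypo
    on the hypomethylated component), reflecting the empirical bimodality of
    CpG methylation.  Per-sample shifts act on the logit scale: the global
    demethylation shift applies to the cocaine-exposed F0 groups
    (Addict-F0, Non-addict-F0); planted sites additionally shift Addict
    samples by a signed effect — in F0 for all planted sites, in F1 only for
    the maintained subset.  Coverage is negative binomial and methylated
    counts beta-binomial with intra-site correlation ``overdispersion``.
    """

    n_sites: int = 10_000
    samples_per_group: dict = field(
        default_factory=lambda: {
            "Saline-F0": 3,
            "Addict-F0": 3,
            "Non-addict-F0": 3,
            "Addict-F1": 3,
            "Non-addict-F1": 4,
        }
    )
    weight_hypo: float = 0.6
    beta_hypo: tuple = (0.5, 10.0)
    beta_hyper: tuple = (10.0, 0.5)
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    global_demethylation_shift: float = -0.3
    n_planted_dmcs: int = 200
    planted_effect: float = 1.5
    maintenance_fraction: float = 0.8
    overdispersion: float = 0.05
    # optional placement control (needs a gene model): probability a
    # planted / background site falls inside a promoter window
    planted_promoter_fraction: float | None = None
    background_promoter_fraction: float | None = None
    promoter_window: int = 2000
    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 3_000_000, "chr2": 2_000_000})
    seed: int = 0

    def validate(self) -> None:
        missing = set(METHYL_GROUPS) - set(self.samples_per_group)
        if missing:
            raise ConfigurationError(f"samples_per_group missing groups: {sorted(missing)}")
        if self.n_planted_dmcs > self.n_sites:
            raise ConfigurationError("n_planted_dmcs must not exceed n_sites")
        if not 0.0 <= self.maintenance_fraction <= 1.0:
            raise ConfigurationError("maintenance_fraction must lie in [0, 1]")
        if not 0.0 < self.weight_hypo < 1.0:
            raise ConfigurationError("weight_hypo must lie in (0, 1)")
        if not 0.0 <= self.overdispersion < 1.0:
            raise ConfigurationError("overdispersion must lie in [0, 1)")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ConfigurationError("coverage parameters must be strictly positive")
        if self.global_demethylation_shift > 0:
            raise ConfigurationError("global_demethylation_shift must be <= 0")


@dataclass
class GroundTruth:
    """Planted structure of a simulated methylome.

    site_ids are "chrom:pos" strings; signs map planted site id -> +1/-1
    (sign of the Addict-minus-Non-addict logit shift); baseline maps site
    id -> the baseline methylation fraction actually used (post-clipping).
    """

    planted_site_ids: set
    maintained_site_ids: set
    signs: dict
    baseline: dict

    def __post_init__(self):
        if not self.maintained_site_ids <= self.planted_site_ids:
            raise ConfigurationError("maintained sites must be a subset of planted sites")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid in sorted(self.planted_site_ids):
            chrom, pos = sid.rsplit(":", 1)
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(pos),
                    "sign": self.signs[sid],
                    "maintained": sid in self.maintained_site_ids,
                    "baseline": self.baseline[sid],
                }
            )
        return pd.DataFrame(rows, columns=["chrom", "pos", "sign", "maintained", "baseline"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GroundTruth":
        sid = df["chrom"].astype(str) + ":" + df["pos"].astype(str)
        return cls(
            set(sid),
            set(sid[df["maintained"].astype(bool)]),
            dict(zip(sid, df["sign"].astype(int))),
            dict(zip(sid, df["baseline"].astype(float))),
        )


def _sample_positions(cfg: MethylSimConfig, rng, gene_model: GeneModel | None):
    """Draw n_sites distinct (chrom, pos), flagging which are planted.

    Without a gene model (or placement fractions) positions are uniform over
    the chromosome sizes.  With placement control, planted and background
    sites are drawn from promoter windows with their respective
    probabilities.
    """
    n = cfg.n_sites
    n_planted = cfg.n_planted_dmcs
    chroms = list(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=np.int64)

    use_placement = (
        gene_model is not None
        and cfg.planted_promoter_fraction is not None
        and cfg.background_promoter_fraction is not None
        and len(gene_model) > 0
    )

    def draw_uniform(k):
        ci = rng.choice(len(chroms), size=k, p=sizes / sizes.sum())
        pos = rng.integers(0, sizes[ci])
        return [(chroms[c], int(p)) for c, p in zip(ci, pos)]

    if not use_placement:
        seen = {}
        order = 0
        planted_flags = np.zeros(n, dtype=bool)
        planted_flags[:n_planted] = True  # first draws are the planted ones
        out = []
        while len(out) < n:
            for cp in draw_uniform(n - len(out)):
                if cp not in seen:
                    seen[cp] = True
                    out.append(cp)
        return out[:n_planted], out[n_planted:]

    genes = gene_model.genes
    tss = gene_model.tss
    windows = []
    for g in range(len(genes)):
        chrom = genes.at[g, "chrom"]
        if chrom not in cfg.chrom_sizes:
            continue
        lo = max(0, int(tss[g]) - cfg.promoter_window)
        hi = min(cfg.chrom_sizes[chrom] - 1, int(tss[g]) + cfg.promoter_window)
        windows.append((chrom, lo, hi))
    if not windows:
        raise ConfigurationError("gene model has no genes on the simulated chromosomes")

    def draw_promoter(k):
        wi = rng.integers(0, len(windows), size=k)
        return [
            (windows[w][0], int(rng.integers(windows[w][1], windows[w][2] + 1))) for w in wi
        ]

    def draw_set(k, prom_frac):
        out = []
        seen = set()
        while len(out) < k:
            want = k - len(out)
            in_prom = rng.random(want) < prom_frac
            cand = []
            n_prom = int(in_prom.sum())
            if n_prom:
                cand += draw_promoter(n_prom)
            if want - n_prom:
                cand += draw_uniform(want - n_prom)
            for cp in cand:
                if cp not in seen and cp not in all_seen:
                    seen.add(cp)
                    out.append(cp)
        all_seen.update(seen)
        return out

    all_seen = set()
    planted = draw_set(n_planted, cfg.planted_promoter_fraction)
    background = draw_set(n - n_planted, cfg.background_promoter_fraction)
    return planted, background


def simulate_methyl_matrix(
    cfg: MethylSimConfig, gene_model: GeneModel | None = None
) -> tuple[MethylMatrix, GroundTruth]:
    """Simulate an RRBS-like count matrix plus its planted ground truth."""
    cfg.validate()
    rng_base = rng_for(cfg.seed, "methylome-baseline")
    rng_plant = rng_for(cfg.seed, "methylome-planted")
    rng_counts = rng_for(cfg.seed, "methylome-counts")
    rng_pos = rng_for(cfg.seed, "methylome-positions")

    n = cfg.n_sites
    planted_pos, background_pos = _sample_positions(cfg, rng_pos, gene_model)
    site_list = planted_pos + background_pos
    planted_mask_unsorted = np.zeros(n, dtype=bool)
    planted_mask_unsorted[: len(planted_pos)] = True

    # baseline methylation: bimodal Beta mixture, clipped away from {0,1}
    comp = rng_base.random(n) < cfg.weight_hypo
    pi0 = np.where(
        comp,
        rng_base.beta(*cfg.beta_hypo, size=n),
        rng_base.beta(*cfg.beta_hyper, size=n),
    )
    pi0 = np.clip(pi0, 1e-3, 1 - 1e-3)

    signs = np.where(rng_plant.random(n) < 0.5, 1, -1)
    n_maint = int(round(cfg.maintenance_fraction * cfg.n_planted_dmcs))
    maint_unsorted = np.zeros(n, dtype=bool)
    if cfg.n_planted_dmcs:
        planted_idx = np.flatnonzero(planted_mask_unsorted)
        chosen = rng_plant.choice(planted_idx, size=n_maint, replace=False)
        maint_unsorted[chosen] = True

    # sort sites by (chrom, pos) carrying flags along
    order = sorted(range(n), key=lambda i: site_list[i])
    site_list = [site_list[i] for i in order]
    pi0 = pi0[order]
    signs = signs[order]
    planted_mask = planted_mask_unsorted[np.array(order)]
    maintained_mask = maint_unsorted[np.array(order)]

    samples = []
    for group in METHYL_GROUPS:
        phenotype, generation = group.rsplit("-", 1)
        for r in range(cfg.samples_per_group[group]):
            samples.append(
                {
                    "sample_id": f"{group}-s{r + 1}",
                    "generation": generation,
                    "phenotype": phenotype,
                }
            )
    samples = pd.DataFrame(samples)
    nsamp = len(samples)

    base_logit = logit(pi0)
    meth = np.zeros((n, nsamp), dtype=np.int64)
    total = np.zeros((n, nsamp), dtype=np.int64)
    for j, row in samples.iterrows():
        shift = np.zeros(n)
        if row["generation"] == "F0" and row["phenotype"] in ("Addict", "Non-addict"):
            shift += cfg.global_demethylation_shift
        if row["phenotype"] == "Addict":
            effect_mask = planted_mask if row["generation"] == "F0" else maintained_mask
            shift = shift + np.where(effect_mask, signs * cfg.planted_effect, 0.0)
        pi = expit(base_logit + shift)
        cov = _nb_draw(rng_counts, np.full(n, cfg.coverage_mean), cfg.coverage_dispersion)
        if cfg.overdispersion > 0:
            a = (1.0 - cfg.overdispersion) / cfg.overdispersion
            p = rng_counts.beta(np.maximum(pi * a, 1e-12), np.maximum((1 - pi) * a, 1e-12))
        else:
            p = pi
        meth[:, j] = rng_counts.binomial(cov, p)
        total[:, j] = cov

    sites = pd.DataFrame(site_list, columns=["chrom", "pos"])
    matrix = MethylMatrix(sites, meth, total, samples)
    sid = sites["chrom"].astype(str) + ":" + sites["pos"].astype(str)
    truth = GroundTruth(
        planted_site_ids=set(sid[planted_mask]),
        maintained_site_ids=set(sid[maintained_mask]),
        signs={s: int(g) for s, g in zip(sid[planted_mask], signs[planted_mask])},
        baseline={s: float(b) for s, b in zip(sid[planted_mask], pi0[planted_mask])},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# gene model and expression table (pipeline plumbing)


def simulate_gene_model(
    n_genes: int = 120,
    chrom_sizes: dict | None = None,
    gene_length: tuple = (5_000, 50_000),
    n_exons: tuple = (2, 8),
    seed: int = 0,
) -> GeneModel:
    """Random non-overlapping gene models on the simulated chromosomes."""
    chrom_sizes = chrom_sizes or {"chr1": 3_000_000, "chr2": 2_000_000}
    rng = rng_for(seed, "gene-model")
    rows = []
    gi = 0
    chroms = list(chrom_sizes)
    per_chrom = {c: n_genes // len(chroms) + (1 if i < n_genes % len(chroms) else 0) for i, c in enumerate(chroms)}
    for chrom in chroms:
        size = chrom_sizes[chrom]
        cursor = 10_000
        for _ in range(per_chrom[chrom]):
            length = int(rng.integers(gene_length[0], gene_length[1] + 1))
            gap = int(rng.integers(5_000, 25_000))
            start = cursor + gap
            end = start + length
            if end > size - 10_000:
                break
            k = int(rng.integers(n_exons[0], n_exons[1] + 1))
            cuts = np.sort(rng.choice(np.arange(1, length), size=2 * k, replace=False))
            ex_s = (start + cuts[0::2]).tolist()
            ex_e = (start + cuts[1::2]).tolist()
            ex_s[0] = start
            ex_e[-1] = end
            rows.append(
                {
                    "gene_id": f"G{gi:04d}",
                    "chrom": chrom,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "start": start,
                    "end": end,
                    "exon_starts": ex_s,
                    "exon_ends": ex_e,
                }
            )
            gi += 1
            cursor = end
    return GeneModel(pd.DataFrame(rows))


def simulate_de_table(
    gene_ids,
    enriched_genes=None,
    p_de_enriched: float = 0.6,
    p_de_background: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic differential-expression results (gene_id, fold_change, p_value).

    Genes in ``enriched_genes`` (e.g. those with maintained promoter DMCs)
    become DE — fold change >= 2 with p < 0.05 — with elevated probability,
    so the methylation-expression overlap stage has signal to find.  This is
    pipeline plumbing for end-to-end runs, not a model of RNA-seq noise.
    """
    enriched_genes = set(enriched_genes or ())
    rng = rng_for(seed, "de-table")
    rows = []
    for g in gene_ids:
        is_de = rng.random() < (p_de_enriched if g in enriched_genes else p_de_background)
        if is_de:
            fc = float(2.0 * np.exp(rng.exponential(0.5)))
            p = float(rng.uniform(1e-6, 0.049))
        else:
            fc = float(np.exp(rng.normal(0.0, 0.25)))
            p = float(rng.uniform(0.05, 1.0))
        rows.append({"gene_id": g, "fold_change": fc, "p_value": p})
    return pd.DataFrame(rows)
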