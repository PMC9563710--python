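"""Synthetic study-design generators with planted ground truth.

Emulates the study layout — two purebred parental lines and their two
reciprocal hybrids, four replicate small-RNA libraries each — so every
downstream stage can be validated against known truth:

* negative-binomial miRNA count matrices with inheritance modes planted
  in the genotype means (variance mu + phi*mu^2),
* daily egg-laying records from a two-state Markov chain with tunable
  clutch persistence,
* mRNA profiles with planted anti-correlations to chosen miRNAs plus an
  accompanying target table and gene sets with planted enrichment,
* FASTQ read sets regenerated from mature sequences for exercising the
  quantification stage end to end.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ROLES, log

__all__ = [
    "SimParams",
    "PlantedMode",
    "LaySimParams",
    "simulate_counts",
    "simulate_lay_records",
    "simulate_mrna",
    "make_gene_sets",
    "generate_fastq",
    "random_mature_set",
]

PLANTABLE_MODES = (
    "additive", "hp_dominant", "lp_dominant",
    "over_dominant", "under_dominant", "conserved",
)


@dataclass(frozen=True)
class SimParams:
    """Count-simulation design: replicates per genotype, expected library
    size, NB dispersion phi (variance = mu + phi*mu^2), total miRNAs."""

    n_replicates: int = 4
    library_size: int = 1_000_000
    dispersion: float = 0.1
    n_mirnas: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass(frozen=True)
class PlantedMode:
    """One miRNA's planted inheritance pattern.

    ``effect`` is the fold change between the parental means (and the
    hybrid's offset from the relevant parent for over/under-dominance);
    ``hybrid_scope`` restricts non-additive placement to one reciprocal
    hybrid or applies it to both.
    """

    mirna_id: str
    mode: str
    hybrid_scope: str = "both"  # H12 | H21 | both
    effect: float = 8.0

    def __post_init__(self) -> None:
        if self.mode not in PLANTABLE_MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.hybrid_scope not in ("H12", "H21", "both"):
            raise ValueError(f"unknown hybrid_scope {self.hybrid_scope!r}")
        if self.mode != "conserved" and self.effect < 1:
            raise ValueError("effect must be >= 1")


@dataclass(frozen=True)
class LaySimParams:
    """Two-state Markov-chain laying model per genotype.

    ``p_lay`` is P(lay | no egg yesterday); ``persistence`` is
    P(lay | laid yesterday), i.e. the probability of continuing a
    clutch.  Scalars apply to every genotype; dicts are per genotype.
    Day 0 starts from the chain's stationary distribution.
    """

    p_lay: float | dict = 0.7
    persistence: float | dict = 0.8
    n_hens: int = 20
    n_days: int = 100
    seed: int = 0
    genotypes: tuple[str, ...] = ROLES

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for g in self.genotypes:
            for v in (self.rate(g), self.persist(g)):
                if not 0 <= v <= 1:
                    raise ValueError("probabilities must lie in [0, 1]")

    def rate(self, genotype: str) -> float:
        return self.p_lay[genotype] if isinstance(self.p_lay, dict) else self.p_lay

    def persist(self, genotype: str) -> float:
        return (
            self.persistence[genotype]
            if isinstance(self.persistence, dict)
            else self.persistence
        )


def stationary_lay_rate(p_lay: float, persistence: float) -> float:
    """Stationary probability of a laying day for the two-state chain."""
    if p_lay == 0:
        return 0.0
    denom = p_lay + 1.0 - persistence
    return 1.0 if denom == 0 else p_lay / denom


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _planted_means(base: float, pm: PlantedMode) -> dict[str, float]:
    """Per-role expected CPM implementing one planted mode exactly.

    Over/under-dominance keep the parents equal, so the out-of-scope
    hybrid sits at the shared parental level (truly conserved there).
    Additive and dominance modes separate the parents ``effect``-fold;
    the out-of-scope hybrid is placed at mid-parent (truly additive
    there).
    """
    lo, hi = base, base * pm.effect
    mid = (lo + hi) / 2.0
    means = {}
    if pm.mode == "conserved":
        return {r: base for r in ROLES}
    if pm.mode in ("over_dominant", "under_dominant"):
        means["P1"] = means["P2"] = base
        planted = base * pm.effect if pm.mode == "over_dominant" else base / pm.effect
        rest = base
    else:
        means["P1"], means["P2"] = lo, hi
        rest = mid
        if pm.mode == "additive":
            planted = mid
        elif pm.mode == "hp_dominant":
            planted = hi
        else:  # lp_dominant
            planted = lo
    for h in ("H12", "H21"):
        in_scope = pm.hybrid_scope in (h, "both") or pm.mode == "additive"
        means[h] = planted if in_scope else rest
    return means


def _truth_mode(pm: PlantedMode, hybrid: str) -> str:
    if pm.mode == "conserved":
        return "conserved"
    if pm.hybrid_scope in (hybrid, "both") or pm.mode == "additive":
        return pm.mode
    # out-of-scope hybrid: mid-parent when parents differ, parental level otherwise
    return "conserved" if pm.mode in ("over_dominant", "under_dominant") else "additive"


def simulate_counts(
    params: SimParams,
    planted: list[PlantedMode],
    planted_cpm_range: tuple[float, float] = (20.0, 500.0),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix around planted genotype means.

    Parental high/low assignment is randomized per miRNA.  Planted
    miRNAs get log-uniform baselines inside ``planted_cpm_range`` —
    moderately expressed, as differential miRNAs tend to be — while the
    heavy-tailed lognormal background carries the bulk of the library
    mass, so planted fold changes perturb library composition only
    marginally.  Per-library totals jitter uniformly within +-10% of
    ``library_size``.

    Returns ``(counts, samples, truth)``: counts is miRNA x sample,
    samples maps sample to genotype/replicate, truth has one row per
    (miRNA, hybrid) with the true mode and the exact planted per-role
    mean CPM.
    """
    ids = [pm.mirna_id for pm in planted]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate mirna_id in planted modes")
    if len(planted) > params.n_mirnas:
        raise ValueError("more planted modes than miRNAs")
    rng = np.random.default_rng(params.seed)

    n_bg = params.n_mirnas - len(planted)
    all_ids = ids + [f"bg-mir-{i + 1:04d}" for i in range(n_bg)]

    lo_cpm, hi_cpm = planted_cpm_range
    base = np.empty(params.n_mirnas)
    base[: len(planted)] = np.exp(
        rng.uniform(np.log(lo_cpm), np.log(hi_cpm), size=len(planted))
    )
    # background fills the remaining library mass with a skewed profile
    bg_raw = rng.lognormal(mean=0.0, sigma=1.5, size=n_bg)
    bg_mass = max(1e6 - base[: len(planted)].sum(), 0.2e6)
    if n_bg:
        base[len(planted):] = np.maximum(bg_raw / bg_raw.sum() * bg_mass, 1.0)

    mean_cpm = np.zeros((params.n_mirnas, len(ROLES)))
    truth_rows = []
    role_ix = {r: j for j, r in enumerate(ROLES)}
    swap = rng.random(len(planted)) < 0.5  # which parent is the high one
    for i, pm in enumerate(planted):
        means = _planted_means(base[i], pm)
        if swap[i]:
            means["P1"], means["P2"] = means["P2"], means["P1"]
        for r, v in means.items():
            mean_cpm[i, role_ix[r]] = v
        for h in ("H12", "H21"):
            truth_rows.append(
                {
                    "mirna_id": pm.mirna_id,
                    "hybrid": h,
                    "true_mode": _truth_mode(pm, h),
                    "mean_P1": means["P1"],
                    "mean_P2": means["P2"],
                    "mean_H": means[h],
                    "effect": pm.effect,
                }
            )
    for i in range(len(planted), params.n_mirnas):
        mean_cpm[i, :] = base[i]
        for h in ("H12", "H21"):
            truth_rows.append(
                {
                    "mirna_id": all_ids[i], "hybrid": h, "true_mode": "conserved",
                    "mean_P1": base[i], "mean_P2": base[i], "mean_H": base[i],
                    "effect": 1.0,
                }
            )

    sample_rows = []
    count_cols = {}
    for role in ROLES:
        for rep in range(1, params.n_replicates + 1):
            sid = f"{role}_{rep}"
            sample_rows.append({"sample_id": sid, "genotype": role, "replicate": rep})
            lib = rng.uniform(0.9, 1.1) * params.library_size
            mu = mean_cpm[:, role_ix[role]] * lib / 1e6
            if params.dispersion == 0:
                draws = rng.poisson(mu)
            else:
                r = 1.0 / params.dispersion
                p = r / (r + mu)
                draws = rng.negative_binomial(r, p)
            count_cols[sid] = draws.astype(np.int64)

    counts = pd.DataFrame(count_cols, index=pd.Index(all_ids, name="mirna_id"))
    samples = pd.DataFrame(sample_rows)
    truth = pd.DataFrame(truth_rows)
    log.info(
        "simulate_counts: %d miRNAs (%d planted) x %d libraries",
        params.n_mirnas, len(planted), len(sample_rows),
    )
    return counts, samples, truth


# ---------------------------------------------------------------------------
# lay records
# ---------------------------------------------------------------------------

def simulate_lay_records(params: LaySimParams) -> pd.DataFrame:
    """Daily 0/1 lay records per hen from the two-state Markov chain.

    Returns a table with hen_id, genotype and day_1..day_n columns.
    Expected egg number per hen is approximately the stationary lay rate
    times ``n_days``.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for g in params.genotypes:
        p, q = params.rate(g), params.persist(g)
        pi1 = stationary_lay_rate(p, q)
        for hen in range(1, params.n_hens + 1):
            u = rng.random(params.n_days)
            days = np.empty(params.n_days, dtype=np.int64)
            days[0] = 1 if u[0] < pi1 else 0
            for t in range(1, params.n_days):
                thresh = q if days[t - 1] == 1 else p
                days[t] = 1 if u[t] < thresh else 0
            row = {"hen_id": f"{g}_hen{hen:03d}", "genotype": g}
            row.update({f"day_{t + 1}": int(v) for t, v in enumerate(days)})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mRNA profiles, targets, gene sets
# ---------------------------------------------------------------------------

def simulate_mrna(
    counts: pd.DataFrame,
    planted_pairs: list[tuple[str, str, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    n_background: int = 50,
    n_decoys: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """mRNA expression with planted anti-correlations plus a target table.

    Each planted (mirna_id, gene_id, target_r) gene is an affine
    *decreasing* function of that miRNA's CPM profile plus Gaussian
    noise; the slope is calibrated so the expected Pearson correlation
    equals ``target_r``.  With ``noise_sd`` zero the realized r is -1
    exactly.  Background genes are independent lognormal profiles.

    The target table lists every planted pair with aggregate score >= 50
    and ``n_decoys`` random (miRNA, background gene) decoy rows scoring
    below 50.
    """
    rng = np.random.default_rng(seed)
    norm = counts / counts.sum(axis=0) * 1e6
    gene_rows: dict[str, np.ndarray] = {}
    target_rows = []
    for mirna_id, gene_id, target_r in planted_pairs:
        if mirna_id not in norm.index:
            raise ValueError(f"unknown mirna_id {mirna_id!r}")
        if not -1 <= target_r < 0:
            raise ValueError("target_r must be in [-1, 0)")
        m = norm.loc[mirna_id].to_numpy(dtype=float)
        sd_m = m.std()
        if noise_sd == 0 or target_r <= -1 or sd_m == 0:
            slope, eps = 1.0, 0.0
        else:
            slope = noise_sd / (sd_m * np.sqrt(1.0 / target_r**2 - 1.0))
            eps = rng.normal(0.0, noise_sd, size=m.size)
        profile = slope * (m.max() - m) + 100.0 + eps
        gene_rows[gene_id] = profile
        target_rows.append(
            {"mirna_id": mirna_id, "gene_id": gene_id,
             "aggregate_score": float(rng.uniform(50.0, 100.0))}
        )
    n_samples = norm.shape[1]
    bg_ids = [f"BGGENE{i + 1:04d}" for i in range(n_background)]
    for gid in bg_ids:
        gene_rows[gid] = rng.lognormal(mean=4.0, sigma=0.5, size=n_samples)
    mirna_ids = list(norm.index)
    for _ in range(n_decoys):
        target_rows.append(
            {
                "mirna_id": mirna_ids[rng.integers(len(mirna_ids))],
                "gene_id": bg_ids[rng.integers(len(bg_ids))],
                "aggregate_score": float(rng.uniform(10.0, 49.99)),
            }
        )
    mrna = pd.DataFrame(gene_rows, index=norm.columns).T
    mrna.index.name = "gene_id"
    targets = pd.DataFrame(target_rows).drop_duplicates(["mirna_id", "gene_id"])
    return mrna, targets.reset_index(drop=True)


def make_gene_sets(
    planted_genes: list[str],
    background_genes: list[str],
    n_enriched: int = 2,
    n_null: int = 8,
    set_size: int = 20,
    seed: int = 0,
) -> list:
    """Gene sets with planted enrichment for the planted genes.

    Enriched sets draw most members from ``planted_genes``; null sets
    draw uniformly from the background.
    """
    from .downstream import GeneSet

    rng = np.random.default_rng(seed)
    pool = list(background_genes)
    sets = []
    for i in range(n_enriched):
        k = min(len(planted_genes), max(2, set_size // 2))
        members = list(rng.choice(planted_genes, size=k, replace=False))
        members += list(rng.choice(pool, size=max(0, set_size - k), replace=False))
        sets.append(GeneSet(f"SET:ENR{i + 1}", f"planted-enriched set {i + 1}",
                            frozenset(members)))
    for i in range(n_null):
        members = rng.choice(pool, size=min(set_size, len(pool)), replace=False)
        sets.append(GeneSet(f"SET:NULL{i + 1}", f"background set {i + 1}",
                            frozenset(members)))
    return sets


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def random_mature_set(n: int = 10, length: int = 22, seed: int = 0,
                      min_pairwise_hamming: int = 5):
    """Random well-separated mature miRNA sequences (DNA alphabet).

    Rejection-samples until all pairwise Hamming distances reach
    ``min_pairwise_hamming``, so single-substitution reads cannot cross
    over between miRNAs.
    """
    from .quantify import MatureSet

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs: list[str] = []
    while len(seqs) < n:
        cand = "".join(rng.choice(bases, size=length))
        if all(sum(a != b for a, b in zip(cand, s)) >= min_pairwise_hamming
               for s in seqs if len(s) == len(cand)):
            seqs.append(cand)
    return MatureSet({f"syn-mir-{i + 1:03d}": s for i, s in enumerate(seqs)})


def generate_fastq(
    mature,
    per_mirna_counts: dict[str, int],
    adapter: str,
    error_rate: float = 0.0,
    seed: int = 0,
    path=None,
) -> list[str]:
    """FASTQ reads regenerated from mature sequences.

    Each read is the mature sequence (U normalized to T), with exactly
    one random substitution at probability ``error_rate``, followed by
    the 3' adapter; qualities are uniform Phred 40.  Writes 4-line
    records to ``path`` when given and returns the records as a list of
    strings.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    rng = np.random.default_rng(seed)
    records = []
    for mid, n_reads in per_mirna_counts.items():
        if mid not in mature.sequences:
            raise ValueError(f"unknown mature id {mid!r}")
        seq = mature.sequences[mid].replace("U", "T")
        if not 18 <= len(seq) <= 30:
            raise ValueError(f"{mid}: mature length outside 18-30 nt")
        for i in range(n_reads):
            read = seq
            if rng.random() < error_rate:
                pos = int(rng.integers(len(read)))
                alt = rng.choice([b for b in "ACGT" if b != read[pos]])
                read = read[:pos] + alt + read[pos + 1 :]
            full = read + adapter
            records.append(
                f"@{mid}:read{i + 1}\n{full}\n+\n{'I' * len(full)}\n"
            )
    if path is not None:
        with open(path, "w") as fh:
            fh.writelines(records)
    return records
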