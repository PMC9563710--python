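"""Shared configuration: thresholds, genotype roles, pipeline config, logging.

All tunable cut-offs of the analysis live here with the study's values as
defaults: the DE gates (q < 0.05, |log2 ratio| >= 1), the low-expression
filter (< 10 CPM in all libraries), the target-score gate (aggregate score
>= 50), the network bound (r <= -0.9) and the enrichment FDR (0.05).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

log = logging.getLogger("hetmir")

#: canonical genotype roles used throughout the pipeline
ROLES = ("P1", "P2", "H12", "H21")

#: default mapping from the study's line names to roles
DEFAULT_GENOTYPE_MAP: dict[str, str] = {
    "R": "P1",   # Rhode Island Red
    "W": "P2",   # White Leghorn
    "RW": "H12",
    "WR": "H21",
}


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger once, with stage-tagged lines."""
    if not log.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        log.addHandler(handler)
    log.setLevel(getattr(logging, level.upper()))


@dataclass(frozen=True)
class DEThresholds:
    """Gates for differential-expression calls.

    A miRNA is differentially expressed in a contrast iff q < ``q_max``
    and |log2 fold change| >= ``min_abs_log2fc``; fold changes are computed
    on the CPM scale with ``pseudocount`` added to both groups, and miRNAs
    below ``filter_cpm`` CPM in every library are removed before testing.
    """

    q_max: float = 0.05
    min_abs_log2fc: float = 1.0
    pseudocount: float = 0.5
    filter_cpm: float = 10.0

    def __post_init__(self) -> None:
        for name in ("q_max", "min_abs_log2fc", "pseudocount", "filter_cpm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"DEThresholds.{name} must be positive")


@dataclass(frozen=True)
class QCParams:
    """Read-level quality control for small-RNA libraries.

    Reads are 3'-adapter trimmed, then kept iff the trimmed length is in
    [``min_len``, ``max_len``] and the mean base quality is strictly above
    ``min_mean_phred``.
    """

    min_mean_phred: float = 20.0
    min_len: int = 18
    max_len: int = 30
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"  # Illumina TruSeq small-RNA 3' adapter
    min_adapter_overlap: int = 6
    trim_5prime: bool = False
    adapter_5prime: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")
        if self.min_adapter_overlap < 1:
            raise ValueError("min_adapter_overlap must be >= 1")


@dataclass
class PipelineConfig:
    """One structured config for the whole pipeline run.

    ``genotype_map`` maps the user's line names (e.g. R/W/RW/WR) to the
    roles P1/P2/H12/H21 so the pipeline is not hardwired to one study's
    nomenclature.  Paths may be ``None`` for disabled stages.
    """

    out_dir: str = "hetmir_out"
    seed: int = 0
    genotype_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_MAP)
    )
    # stage toggles
    run_quantify: bool = False
    run_de: bool = True
    run_classify: bool = True
    run_heterosis: bool = True
    run_targets: bool = True
    run_network: bool = True
    # inputs
    counts_path: str | None = None
    samples_path: str | None = None
    fastq_paths: dict[str, str] = field(default_factory=dict)  # sample_id -> fastq
    mature_fasta: str | None = None
    lay_records_path: str | None = None
    targets_path: str | None = None
    expressed_genes_path: str | None = None
    mrna_expr_path: str | None = None
    gene_sets_path: str | None = None
    # thresholds
    de: DEThresholds = field(default_factory=DEThresholds)
    qc: QCParams = field(default_factory=QCParams)
    network_r_max: float = -0.9
    enrich_q_max: float = 0.05
    target_min_score: float = 50.0

    def __post_init__(self) -> None:
        bad = set(self.genotype_map.values()) - set(ROLES)
        if bad:
            raise ValueError(f"genotype_map assigns unknown roles: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw: Mapping = yaml.safe_load(fh) or {}
        raw = dict(raw)
        if "de" in raw:
            raw["de"] = DEThresholds(**raw["de"])
        if "qc" in raw:
            raw["qc"] = QCParams(**raw["qc"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
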