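"""Configuration objects for the simulator and the analysis pipeline.

All tunable thresholds of the pipeline live in :class:`PipelineConfig`;
nothing downstream hard-codes a cutoff.  The simulator's defaults define
the standard synthetic study: two pooled muscle libraries (fetal-like and
adult-like), 2e5 reads each, thirty known and ten novel planted miRNA
hairpins, and twenty known miRNAs planted at a true four-fold change
between the stages (ten up in the fetal library, ten down).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

# Classic Illumina small-RNA adapters; any non-empty sequences work.
DEFAULT_ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"

#: Read share of each non-miRNA locus class in a simulated library
#: (roughly echoing a muscle small-RNA library, where rRNA fragments are
#: the main non-miRNA genome-matched class).
DEFAULT_CLASS_SHARES = {
    "rRNA": 0.10,
    "tRNA": 0.016,
    "snRNA": 0.003,
    "snoRNA": 0.003,
    "scRNA": 0.001,
    "srpRNA": 0.001,
    "repeat": 0.008,
    "exon": 0.008,
    "intron": 0.004,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic small-RNA world."""

    seed: int = 0
    genome_length: int = 300_000
    gc_content: float = 0.42
    n_known_mirna: int = 30
    n_novel_mirna: int = 10
    n_other_loci_per_class: int = 4
    library_sizes: tuple[int, int] = (200_000, 200_000)  # (fetal, adult)
    read_length: int = 36
    length_mode: int = 22
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    # Per-base substitution probability applied to genuine inserts.
    error_rate: float = 0.005
    # Fraction of known-miRNA reads that are end variants (isomiRs).
    isomir_rate: float = 0.15
    # Fraction of known-miRNA reads carrying a single base edit or an
    # untemplated 3' A/U addition.
    edit_rate: float = 0.05
    # Contaminant read fractions (ledger categories of the cleaning step).
    adapter3_null_rate: float = 0.0007
    insert_null_rate: float = 0.0003
    adapter5_contaminant_rate: float = 0.0015
    short_rate: float = 0.024
    polyA_rate: float = 1e-5
    # Read share of the known-miRNA pool in the *adult* library; the fetal
    # share follows from the planted fold changes.
    mirna_share: float = 0.42
    # Total read share of all novel miRNAs (adult library).
    novel_share: float = 0.006
    # A star arm receives this fraction of its mature arm's reads.
    star_fraction: float = 0.08
    # Read share of unannotated genomic fragments / non-genomic junk.
    unknown_genomic_share: float = 0.015
    class_shares: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_SHARES))
    # True fetal/adult expression ratio per known miRNA id; None selects the
    # default plan: first ten at 4.0, next ten at 0.25, remainder at 1.0.
    planted_fold_changes: Optional[dict] = None
    # qPCR simulator: Ct = intercept - log2(abundance) + N(0, noise_sd).
    qpcr_intercept: float = 30.0
    qpcr_noise_sd: float = 0.15

    def validate(self) -> None:
        rates = {
            "error_rate": self.error_rate,
            "isomir_rate": self.isomir_rate,
            "edit_rate": self.edit_rate,
            "adapter3_null_rate": self.adapter3_null_rate,
            "insert_null_rate": self.insert_null_rate,
            "adapter5_contaminant_rate": self.adapter5_contaminant_rate,
            "short_rate": self.short_rate,
            "polyA_rate": self.polyA_rate,
            "gc_content": self.gc_content,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if any(n <= 0 for n in self.library_sizes):
            raise ValueError("library sizes must be positive")
        if not self.adapter3 or not self.adapter5:
            raise ValueError("adapters must be non-empty")


#: Fixed category priority used when a tag overlaps several locus classes.
DEFAULT_PRIORITY = (
    "miRNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "scRNA",
    "srpRNA",
    "repeat",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
    "unknown",
)


@dataclass
class PipelineConfig:
    """Every analysis threshold, in one serialisable place."""

    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    min_len: int = 18
    # 3' adapter located by exact match of its first `adapter3_seed_len` bases.
    adapter3_seed_len: int = 8
    # 5'-contaminant: insert begins with the 5' adapter's last bases.
    adapter5_tail_len: int = 6
    # polyA: insert with at least this A fraction after trimming.
    polya_fraction: float = 0.8
    # Genome index k-mer (also the minimum mappable tag length).
    index_k: int = 18
    annotation_priority: tuple = DEFAULT_PRIORITY
    # Variant-inclusive counting: a hairpin-placed tag counts toward a
    # mature miRNA when it overlaps the mature site by at least this many nt.
    mature_overlap_min: int = 16
    # Novel discovery.
    flank: int = 150
    max_genome_hits: int = 10
    cluster_gap: int = 30
    min_cluster_reads: int = 5
    mature_len_range: tuple[int, int] = (20, 22)
    mfe_max: float = -20.0  # kcal/mol, strict upper bound on precursor MFE
    mfei_min: float = 0.85
    au_range: tuple[float, float] = (0.30, 0.70)
    max_star_mismatches: int = 5  # "less than six mismatches"
    # Differential expression.
    alpha: float = 0.01
    padj_method: str = "fdr_bh"
    pseudo_tpm: float = 0.01
    # qPCR.
    reference_gene: str = "RPS18"
    max_ct: float = 40.0
    ct_outlier_cycles: float = 0.5
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        for key in ("library_sizes",):
            data.pop(key, None)
        for key, value in list(data.items()):
            if isinstance(value, list):
                data[key] = tuple(value)
        return cls(**data)
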