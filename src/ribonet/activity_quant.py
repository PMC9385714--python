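"""From barcoded sequencing reads (or count tables) to relative activities.

The assay sequences each variant twice (duplicate library preparations).
Within each replicate, a read belongs to the ligated or unligated pool
according to an exact barcode match at the start of the read; the variable
catalytic core is excised between two constant flanks and quality-filtered.
Per-variant counts give the fraction ligated FL = N_lig / (N_lig + N_unlig);
dividing by the wild type's FL gives the relative activity RA. Variants
with too few reads in either replicate are discarded; the mean of the two
replicate RAs, with the neutrality call RA >= threshold, is the final
record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from ribonet.sequence_core import Genotype, mutations_between, name_variant

DEFAULT_NEUTRALITY_THRESHOLD = 0.2
DEFAULT_MIN_QUALITY = 20


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self):
        if len(self.qualities) != len(self.sequence):
            raise ValueError("qualities and sequence lengths differ")


@dataclass(frozen=True)
class AssaySpec:
    """Barcodes, flanks and filters defining one sequencing assay.

    ``max_low_quality_bases`` is 1 for the deeply mutated libraries and 0
    otherwise; ``min_total_reads`` is 30 for the distant-anchor library and
    100 for all other libraries.
    """

    ligated_barcode: str
    unligated_barcode: str
    core_flank_5p: str
    core_flank_3p: str
    core_length: int
    max_low_quality_bases: int = 0
    min_total_reads: int = 100
    min_quality: int = DEFAULT_MIN_QUALITY

    def __post_init__(self):
        if self.ligated_barcode == self.unligated_barcode:
            raise ValueError("barcodes must be distinct")
        if self.core_length <= 0:
            raise ValueError("core_length must be positive")


@dataclass
class NeutralityConfig:
    threshold: float = DEFAULT_NEUTRALITY_THRESHOLD

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


def read_fastq(path) -> Iterator[ReadRecord]:
    """Parse a FASTQ file (4-line records, Phred+33) into ReadRecords."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(
            rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"])
        )


def demultiplex(
    reads: Iterable[ReadRecord], spec: AssaySpec
) -> tuple[list[ReadRecord], list[ReadRecord], list[tuple[ReadRecord, str]]]:
    """Sort reads into ligated/unligated pools by exact barcode prefix.

    Unmatched reads are returned with a reason; rejection is data, not an
    error.
    """
    ligated, unligated, rejected = [], [], []
    for read in reads:
        if read.sequence.startswith(spec.ligated_barcode):
            ligated.append(read)
        elif read.sequence.startswith(spec.unligated_barcode):
            unligated.append(read)
        else:
            rejected.append((read, "no_barcode"))
    return ligated, unligated, rejected


def extract_core(read: ReadRecord, spec: AssaySpec) -> Genotype | None:
    """Excise the variable core between the constant flanks, or reject.

    Rejects (returns None) when a flank is absent, the excised region has
    the wrong length, or more than ``max_low_quality_bases`` base calls in
    the variable region fall below the quality cutoff. Flank matching is
    exact.
    """
    start = read.sequence.find(spec.core_flank_5p)
    if start < 0:
        return None
    core_start = start + len(spec.core_flank_5p)
    core_end = core_start + spec.core_length
    if read.sequence[core_end : core_end + len(spec.core_flank_3p)] != spec.core_flank_3p:
        return None
    core = read.sequence[core_start:core_end]
    if len(core) != spec.core_length:
        return None
    quals = read.qualities[core_start:core_end]
    n_low = sum(q < spec.min_quality for q in quals)
    if n_low > spec.max_low_quality_bases:
        return None
    return core


def count_cores(
    reads: Iterable[ReadRecord], spec: AssaySpec
) -> tuple[dict[Genotype, int], int]:
    """Count extracted core sequences; returns (counts, n_rejected)."""
    counts: dict[Genotype, int] = {}
    rejected = 0
    for read in reads:
        core = extract_core(read, spec)
        if core is None:
            rejected += 1
        else:
            counts[core] = counts.get(core, 0) + 1
    return counts, rejected


def fraction_ligated(n_ligated: int, n_unligated: int) -> float:
    """FL = N_lig / (N_lig + N_unlig)."""
    total = n_ligated + n_unligated
    if total <= 0:
        raise ValueError("zero total reads")
    return n_ligated / total


def relative_activity(fl_variant: float, fl_wt: float) -> float:
    """RA = FL_variant / FL_WT; not capped above 1."""
    if fl_wt <= 0:
        raise ValueError("wild-type FL must be positive")
    return fl_variant / fl_wt


@dataclass
class VariantCounts:
    """Per-replicate ligated/unligated counts for one variant."""

    n_ligated: tuple[int, int]
    n_unligated: tuple[int, int]

    def total(self, replicate: int) -> int:
        return self.n_ligated[replicate] + self.n_unligated[replicate]


@dataclass
class ActivityRecord:
    genotype: Genotype
    fl: tuple[float, float]
    ra: tuple[float, float]
    ra_mean: float
    ra_sd: float
    n_reads: tuple[int, int]
    neutral: bool


def merge_replicates(
    counts: VariantCounts,
    fl_wt: tuple[float, float],
    spec: AssaySpec,
    cfg: NeutralityConfig | None = None,
    genotype: Genotype = "",
) -> ActivityRecord | None:
    """Combine duplicate measurements into one record, or discard.

    The variant is discarded (None) when the total read count in either
    replicate is below ``spec.min_total_reads``. RA_mean is the mean of the
    two replicate RAs; RA_sd is their population standard deviation
    (divisor n); the neutrality flag is RA_mean >= threshold.
    """
    cfg = cfg or NeutralityConfig()
    totals = (counts.total(0), counts.total(1))
    if min(totals) < spec.min_total_reads:
        return None
    fl = tuple(
        fraction_ligated(counts.n_ligated[r], counts.n_unligated[r]) for r in (0, 1)
    )
    ra = tuple(relative_activity(fl[r], fl_wt[r]) for r in (0, 1))
    ra_mean = float(np.mean(ra))
    ra_sd = float(np.std(ra))  # population SD; with n=2 this is |ra0-ra1|/2
    return ActivityRecord(
        genotype=genotype,
        fl=fl,  # type: ignore[arg-type]
        ra=ra,  # type: ignore[arg-type]
        ra_mean=ra_mean,
        ra_sd=ra_sd,
        n_reads=totals,
        neutral=ra_mean >= cfg.threshold,
    )


def quantify_counts(
    counts: Mapping[Genotype, tuple[tuple[int, int], tuple[int, int]]],
    wild_type: Genotype,
    spec: AssaySpec,
    cfg: NeutralityConfig | None = None,
) -> pd.DataFrame:
    """Build the activity table from per-variant replicate counts.

    ``counts`` maps sequence -> ((lig_rep1, unlig_rep1), (lig_rep2,
    unlig_rep2)). The wild type must pass the read-count filter in both
    replicates because every variant's RA is normalized to its FL.
    """
    cfg = cfg or NeutralityConfig()
    if wild_type not in counts:
        raise ValueError("wild-type counts are required for RA normalization")
    (wl1, wu1), (wl2, wu2) = counts[wild_type]
    if min(wl1 + wu1, wl2 + wu2) < spec.min_total_reads:
        raise ValueError("wild type fails the read-count filter")
    fl_wt = (fraction_ligated(wl1, wu1), fraction_ligated(wl2, wu2))

    rows = []
    for seq, ((l1, u1), (l2, u2)) in counts.items():
        rec = merge_replicates(
            VariantCounts(n_ligated=(l1, l2), n_unligated=(u1, u2)),
            fl_wt,
            spec,
            cfg,
            genotype=seq,
        )
        if rec is None:
            continue
        rows.append(
            {
                "variant_name": name_variant(mutations_between(wild_type, seq))
                if len(seq) == len(wild_type)
                else seq,
                "sequence": seq,
                "FL_rep1": rec.fl[0],
                "FL_rep2": rec.fl[1],
                "RA_mean": rec.ra_mean,
                "RA_sd": rec.ra_sd,
                "n_reads_rep1": rec.n_reads[0],
                "n_reads_rep2": rec.n_reads[1],
                "neutral": rec.neutral,
            }
        )
    return pd.DataFrame(rows)


def quantify_fastq(
    fastq_rep1,
    fastq_rep2,
    wild_type: Genotype,
    spec: AssaySpec,
    cfg: NeutralityConfig | None = None,
) -> pd.DataFrame:
    """Full pipeline from two replicate FASTQ files to the activity table.

    Each FASTQ holds one replicate; within a file the ligated/unligated
    pools are separated by barcode. Replicate pairing is by file.
    """
    counts: dict[Genotype, list[list[int]]] = {}
    for rep, path in enumerate((fastq_rep1, fastq_rep2)):
        ligated, unligated, _ = demultiplex(read_fastq(path), spec)
        for pool_idx, pool in enumerate((ligated, unligated)):
            pool_counts, _ = count_cores(pool, spec)
            for seq, n in pool_counts.items():
                per = counts.setdefault(seq, [[0, 0], [0, 0]])
                per[rep][pool_idx] += n
    tidy = {
        seq: ((c[0][0], c[0][1]), (c[1][0], c[1][1])) for seq, c in counts.items()
    }
    return quantify_counts(tidy, wild_type, spec, cfg)


def read_count_table(path) -> dict[Genotype, tuple[tuple[int, int], tuple[int, int]]]:
    """Load a pre-counted TSV (variant, replicate, N_ligated, N_unligated)."""
    df = pd.read_csv(path, sep="\t")
    counts: dict[Genotype, dict[int, tuple[int, int]]] = {}
    for _, row in df.iterrows():
        counts.setdefault(row["variant"], {})[int(row["replicate"])] = (
            int(row["N_ligated"]),
            int(row["N_unligated"]),
        )
    out = {}
    for seq, reps in counts.items():
        if set(reps) != {1, 2}:
            raise ValueError(f"variant {seq!r} lacks one of the two replicates")
        out[seq] = (reps[1], reps[2])
    return out


def landscape_from_activity_table(table: pd.DataFrame, wild_type: Genotype):
    """Convenience: activity table -> Landscape keyed by sequence."""
    from ribonet.landscape import Landscape

    return Landscape(dict(zip(table["sequence"], table["RA_mean"])), wild_type)
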