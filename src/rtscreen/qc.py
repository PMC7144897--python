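"""Per-well sequencing quality-control metrics for 5'-end (CAGE-style) screens.

Six metrics are computed for every well from its demultiplexed read pairs,
applied as a cascade so that the first four partition the reads exactly:

1. oligonucleotide artefacts — low-complexity reads or reads matching the
   synthetic oligo set (primer dimers, oligo-on-oligo reverse transcription),
   as a percentage of demultiplexed pairs;
2. ribosomal RNA — pairs sharing a k-mer (default k=21) with reference rRNA
   sequences, percentage of demultiplexed pairs;
3. mapping rate — pairs properly aligned to the genome (mates facing head
   to head, 5'-to-5' distance strictly under 2 Mb), percentage of
   demultiplexed pairs;
4. promoter rate — properly mapped pairs whose 5' end falls in a promoter
   window (1000 nt centred on an annotated TSS, strand-matched),
   percentage of properly mapped pairs;
5. strand-invasion rate — UMI-collapsed molecules whose genomic sequence
   immediately upstream of the 5' end matches the TSO 3' tail (template
   switching onto genomic sequence instead of a capped 5' end), percentage
   of molecule counts;
6. richness — Hurlbert's expected number of distinct genes if the well's
   gene-mapped reads were downsampled to 10.

The module never aligns reads itself: properly aligned coordinates come
either from externally produced BED-like records or from the exact-match
placement of error-free synthetic reads.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy.special import gammaln

__all__ = [
    "AlignmentMate",
    "AlignmentRecord",
    "MoleculeRecord",
    "AnnotationSet",
    "QCReport",
    "dinucleotide_entropy",
    "ArtefactClassifier",
    "classify_artefact",
    "RrnaClassifier",
    "classify_rrna",
    "is_proper_pair",
    "umi_collapse",
    "detect_strand_invasion",
    "hurlbert_richness",
    "assign_gene",
    "compute_qc_report",
    "revcomp",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class AlignmentMate:
    """One aligned mate, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.start}..{self.end}")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class AlignmentRecord:
    """A demultiplexed read pair with its (possibly absent) alignments."""

    read_id: str
    umi: str
    mate1: AlignmentMate | None
    mate2: AlignmentMate | None


@dataclass(frozen=True)
class MoleculeRecord:
    """A UMI-deduplicated 5' end."""

    chrom: str
    five_prime: int
    strand: str
    umi: str
    support: int  # reads collapsed into this molecule


@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class AnnotationSet:
    """Gene intervals, promoter windows, rRNA references and the oligo set."""

    genes: list[Gene]
    rrna_refs: dict[str, str]
    oligos: list[str]
    tso_tail: str
    promoter_halfwidth: int = 500
    _trees: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for g in self.genes:
            self._trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(
                g.start, g.end, g
            )
        self._tss = {}
        for g in self.genes:
            self._tss.setdefault((g.chrom, g.strand), []).append(g.tss)
        self._tss = {k: np.array(sorted(v)) for k, v in self._tss.items()}

    def genes_at(self, chrom: str, pos: int, strand: str) -> list[Gene]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        return [iv.data for iv in tree[pos]]

    def in_promoter(self, chrom: str, pos: int, strand: str) -> bool:
        """Within ``promoter_halfwidth`` of a same-strand TSS (window of
        2×halfwidth = 1000 nt centred on the start position)."""
        tss = self._tss.get((chrom, strand))
        if tss is None or tss.size == 0:
            return False
        i = int(np.searchsorted(tss, pos))
        h = self.promoter_halfwidth
        # half-open window [tss - h, tss + h), total width 2h = 1000 nt
        for j in (i - 1, i, i + 1):
            if 0 <= j < tss.size and -h <= pos - int(tss[j]) < h:
                return True
        return False


def dinucleotide_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the overlapping dinucleotide composition.

    Random sequence scores near 4 bits; homopolymers 0, simple repeats ~1.
    """
    if len(seq) < 2:
        return 0.0
    counts = Counter(seq[i : i + 2] for i in range(len(seq) - 1))
    n = len(seq) - 1
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


class ArtefactClassifier:
    """Oligonucleotide-artefact filter: low dinucleotide entropy, or a
    >= k-mer exact match (default k=16) to any oligo of the synthesis set
    or its reverse complement, in either mate.

    The entropy criterion is only applied to mates of at least
    ``entropy_min_len`` nt (default 30): a 21-nt mate offers too few
    dinucleotides for a stable complexity estimate and occasionally dips
    below threshold on genuine genomic sequence.
    """

    def __init__(
        self,
        oligos: list[str],
        k: int = 16,
        entropy_threshold: float = 2.0,
        entropy_min_len: int = 30,
    ):
        if not oligos:
            raise ValueError("empty oligo list")
        self.k = k
        self.entropy_threshold = entropy_threshold
        self.entropy_min_len = entropy_min_len
        self.kmers: set[str] = set()
        for o in oligos:
            for s in (o.upper(), revcomp(o.upper())):
                for i in range(len(s) - k + 1):
                    self.kmers.add(s[i : i + k])

    def _kmer_hit(self, seq: str) -> bool:
        k = self.k
        return any(seq[i : i + k] in self.kmers for i in range(len(seq) - k + 1))

    def flag(self, read1: str, read2: str = "") -> bool:
        for seq in (read1, read2):
            if not seq:
                continue
            if (
                len(seq) >= self.entropy_min_len
                and dinucleotide_entropy(seq) < self.entropy_threshold
            ):
                return True
            if self._kmer_hit(seq.upper()):
                return True
        return False


def classify_artefact(
    read1: str,
    read2: str,
    oligos: list[str],
    entropy_threshold: float = 2.0,
    k: int = 16,
) -> bool:
    return ArtefactClassifier(oligos, k, entropy_threshold).flag(read1, read2)


class RrnaClassifier:
    """rRNA filter by k-mer containment (default k=21, both strands)."""

    def __init__(self, rrna_refs: dict[str, str], k: int = 21):
        self.k = k
        self.kmers: set[str] = set()
        for ref in rrna_refs.values():
            for s in (ref.upper(), revcomp(ref.upper())):
                for i in range(len(s) - k + 1):
                    self.kmers.add(s[i : i + k])

    def flag(self, read1: str, read2: str = "") -> bool:
        k = self.k
        for seq in (read1, read2):
            if any(seq[i : i + k].upper() in self.kmers for i in range(len(seq) - k + 1)):
                return True
        return False


def classify_rrna(read1: str, read2: str, rrna_refs: dict[str, str], k: int = 21) -> bool:
    if any(k > len(r) for r in (read1, read2) if r):
        raise ValueError(f"k={k} exceeds read length")
    return RrnaClassifier(rrna_refs, k).flag(read1, read2)


def is_proper_pair(
    mate1: AlignmentMate,
    mate2: AlignmentMate,
    max_distance: int = 2_000_000,
) -> bool:
    """Properly aligned: same chromosome, mates facing head to head
    (forward–reverse, each 3' end pointing toward the other mate), and
    5'-to-5' distance strictly below ``max_distance`` (2 Mb)."""
    if mate1.chrom != mate2.chrom or mate1.strand == mate2.strand:
        return False
    fwd, rev = (mate1, mate2) if mate1.strand == "+" else (mate2, mate1)
    if rev.five_prime < fwd.five_prime:
        return False  # diverging, not facing
    return abs(mate1.five_prime - mate2.five_prime) < max_distance


def umi_collapse(records: list[AlignmentRecord]) -> list[MoleculeRecord]:
    """One molecule per distinct (chrom, 5' position, strand, UMI) of the
    first mate; PCR duplicates collapse with their read support recorded."""
    groups: Counter = Counter()
    for r in records:
        if r.mate1 is None:
            continue
        groups[(r.mate1.chrom, r.mate1.five_prime, r.mate1.strand, r.umi)] += 1
    return [
        MoleculeRecord(chrom, pos, strand, umi, n)
        for (chrom, pos, strand, umi), n in sorted(groups.items())
    ]


def detect_strand_invasion(
    molecule: MoleculeRecord,
    genome: dict[str, str],
    tso_tail: str,
    max_mismatch: int = 2,
) -> bool:
    """True when the genomic sequence directly upstream of the molecule's 5'
    end (strand-aware, length = |tail|) matches the TSO 3' tail with at most
    ``max_mismatch`` substitutions — the signature of the template-switching
    oligo having invaded at an internal genomic site.  Molecules too close
    to the contig edge for a full upstream window are not flagged."""
    tail = tso_tail.upper()
    L = len(tail)
    chrom_seq = genome[molecule.chrom]
    if molecule.strand == "+":
        if molecule.five_prime < L:
            return False
        upstream = chrom_seq[molecule.five_prime - L : molecule.five_prime]
    else:
        if molecule.five_prime + 1 + L > len(chrom_seq):
            return False
        upstream = revcomp(chrom_seq[molecule.five_prime + 1 : molecule.five_prime + 1 + L])
    mismatches = sum(a != b for a, b in zip(upstream.upper(), tail))
    return mismatches <= max_mismatch


def hurlbert_richness(gene_counts, n: int = 10) -> float | None:
    """Hurlbert's rarefaction: expected number of distinct genes when the
    library is downsampled to ``n`` reads without replacement.

        E[S_n] = sum_i [ 1 - C(N - N_i, n) / C(N, n) ],  N = sum_i N_i

    Computed in log space for stability.  Returns None when N < n
    (the expectation is undefined at that depth).
    """
    counts = np.asarray(
        list(gene_counts.values()) if isinstance(gene_counts, dict) else gene_counts,
        dtype=float,
    )
    if counts.size == 0:
        return None
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise ValueError("gene counts must be non-negative integers")
    counts = counts[counts > 0]
    N = counts.sum()
    if N < n:
        return None

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    keep = counts <= N - n  # classes with N_i > N - n are always observed
    terms = np.ones_like(counts)
    if np.any(keep):
        terms[keep] = 1.0 - np.exp(log_comb(N - counts[keep], n) - log_comb(N, n))
    return float(terms.sum())


def assign_gene(
    chrom: str, pos: int, strand: str, annotation: AnnotationSet
) -> str | None:
    """Gene whose interval contains the 5' position on the same strand.

    Ties (overlapping genes) break by longest overlap with the containing
    interval, then lexicographic gene id."""
    hits = annotation.genes_at(chrom, pos, strand)
    if not hits:
        return None
    hits.sort(key=lambda g: (-(g.end - g.start), g.gene_id))
    return hits[0].gene_id


@dataclass
class QCReport:
    """Six quality metrics for one well, with the denominators used."""

    plate_id: str
    well: str
    extracted_pairs: int
    artefact_pct: float | None = None
    rrna_pct: float | None = None
    mapping_pct: float | None = None
    promoter_pct: float | None = None
    strand_invasion_pct: float | None = None
    richness_at_10: float | None = None
    n_properly_mapped: int = 0
    n_molecules: int = 0
    n_gene_reads: int = 0

    def as_dict(self) -> dict:
        return {
            "plate_id": self.plate_id,
            "well": self.well,
            "extracted_pairs": self.extracted_pairs,
            "artefact_pct": self.artefact_pct,
            "rrna_pct": self.rrna_pct,
            "mapping_pct": self.mapping_pct,
            "promoter_pct": self.promoter_pct,
            "strand_invasion_pct": self.strand_invasion_pct,
            "richness_at_10": self.richness_at_10,
            "n_properly_mapped": self.n_properly_mapped,
            "n_molecules": self.n_molecules,
            "n_gene_reads": self.n_gene_reads,
        }


@dataclass
class QCParams:
    artefact_k: int = 16
    artefact_entropy_threshold: float = 2.0
    rrna_k: int = 21
    max_pair_distance: int = 2_000_000
    si_max_mismatch: int = 2
    rarefy_depth: int = 10


def compute_qc_report(
    plate_id: str,
    well: str,
    pairs,
    annotation: AnnotationSet,
    genome: dict[str, str],
    aligner=None,
    alignments: dict[str, tuple[AlignmentMate | None, AlignmentMate | None]] | None = None,
    params: QCParams = QCParams(),
    _artefact: ArtefactClassifier | None = None,
    _rrna: RrnaClassifier | None = None,
) -> QCReport:
    """Run the classification cascade over one well's demultiplexed pairs.

    ``pairs`` iterates objects with read_id/umi/insert/r2 attributes.
    Alignments for non-artefact, non-rRNA pairs come from ``alignments``
    (read_id keyed) or, failing that, from ``aligner`` — any object with an
    ``align(seq) -> AlignmentMate | None`` method.
    """
    pairs = list(pairs)
    n = len(pairs)
    report = QCReport(plate_id=plate_id, well=well, extracted_pairs=n)
    if n == 0:
        return report

    art = _artefact or ArtefactClassifier(
        annotation.oligos, params.artefact_k, params.artefact_entropy_threshold
    )
    rib = _rrna or RrnaClassifier(annotation.rrna_refs, params.rrna_k)

    n_art = n_rrna = n_mapped = n_promoter = 0
    mapped_records: list[AlignmentRecord] = []
    gene_counts: Counter = Counter()
    for p in pairs:
        if art.flag(p.insert, p.r2):
            n_art += 1
            continue
        if rib.flag(p.insert, p.r2):
            n_rrna += 1
            continue
        if alignments is not None and p.read_id in alignments:
            m1, m2 = alignments[p.read_id]
        elif aligner is not None:
            m1 = aligner.align(p.insert)
            m2 = aligner.align(p.r2)
        else:
            m1 = m2 = None
        if m1 is None or m2 is None or not is_proper_pair(m1, m2, params.max_pair_distance):
            continue
        n_mapped += 1
        mapped_records.append(AlignmentRecord(p.read_id, p.umi, m1, m2))
        if annotation.in_promoter(m1.chrom, m1.five_prime, m1.strand):
            n_promoter += 1
        gene = assign_gene(m1.chrom, m1.five_prime, m1.strand, annotation)
        if gene is not None:
            gene_counts[gene] += 1

    molecules = umi_collapse(mapped_records)
    n_si = sum(
        detect_strand_invasion(m, genome, annotation.tso_tail, params.si_max_mismatch)
        for m in molecules
    )

    report.artefact_pct = 100.0 * n_art / n
    report.rrna_pct = 100.0 * n_rrna / n
    report.mapping_pct = 100.0 * n_mapped / n
    report.promoter_pct = 100.0 * n_promoter / n_mapped if n_mapped else None
    report.strand_invasion_pct = 100.0 * n_si / len(molecules) if molecules else None
    report.n_properly_mapped = n_mapped
    report.n_molecules = len(molecules)
    report.n_gene_reads = sum(gene_counts.values())
    report.richness_at_10 = hurlbert_richness(gene_counts, params.rarefy_depth)
    return report
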