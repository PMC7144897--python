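"""Synthetic references and reads for exercising the screen end to end.

Builds a toy reference (one ~200 kb chromosome, 50 genes with TSS
annotation, two rRNA references, the oligo set) and per-well paired reads
whose class composition follows a parametric response surface over the
screened conditions, together with a truth table, so demultiplexing and QC
can be validated without downloading anything.

Read classes are {artefact, rrna, unmapped, genic, promoter}; their
probabilities are a softmax over logits linear in log-transformed reagent
levels.  The artefact logit carries a log(RTP/TSO) ratio term, so raising
the reverse-transcription primer increases artefacts while a proportional
rise of the template-switching oligo compensates — the diagonal structure
seen in real screens.  Strand-invasion truth is planted: the genome
carries copies of the TSO 3' tail at designated intra-genic sites and a
configured fraction of genic molecules starts directly downstream of one.

The generator emulates error-free reads with fixed lengths (46 nt read 1 =
barcode + UMI + insert, 8 nt index, 21 nt read 2); an optional uniform
substitution rate exercises barcode mismatch handling.  It does not model
quality scores, indels, or PCR-cycle chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demux import INDEX_SEQUENCES, ReadStructure
from .qc import AlignmentMate, AnnotationSet, Gene, revcomp

__all__ = [
    "ToyReference",
    "ResponseModel",
    "build_toy_reference",
    "response_surface",
    "sample_well_reads",
    "ExactMatcher",
    "CLASSES",
]

CLASSES = ("artefact", "rrna", "unmapped", "genic", "promoter")

# constant oligo parts (synthetic stand-ins for a real oligo set)
ADAPTER = "AAGCAGTGGTATCAACGCAGAGT"
RTP_CONST = "GTGACTGGAGTTCAGACGTGTGCTCT"
TSO_TAIL = "AGAGTACGGG"  # 3' tail ending in the riboguanosine-mimicking GGG


@dataclass
class ToyReference:
    genome: dict[str, str]
    genes: list[Gene]
    rrna: dict[str, str]
    oligos: dict[str, str]  # named: adapter, rtp, tso_tail
    invasion_sites: list[tuple[str, int, str]]  # (gene_id, 5' pos, strand)

    @property
    def tso_tail(self) -> str:
        return self.oligos["tso_tail"]

    def annotation(self, promoter_halfwidth: int = 500) -> AnnotationSet:
        return AnnotationSet(
            genes=list(self.genes),
            rrna_refs=dict(self.rrna),
            oligos=[self.oligos["adapter"], self.oligos["rtp"]],
            tso_tail=self.tso_tail,
            promoter_halfwidth=promoter_halfwidth,
        )

    # ---- file forms -------------------------------------------------
    def write_genome_fasta(self, path) -> None:
        _write_fasta(path, self.genome)

    def write_rrna_fasta(self, path) -> None:
        _write_fasta(path, self.rrna)

    def write_genes_bed(self, path) -> None:
        """BED6, 0-based half-open, score column carries 0."""
        with open(path, "w") as fh:
            for g in self.genes:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def _write_fasta(path, seqs: dict[str, str]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def build_toy_reference(
    seed: int = 0,
    chrom_len: int = 200_000,
    chrom_name: str = "chrT",
    n_genes: int = 50,
    gene_length: tuple[int, int] = (1_400, 2_400),
    min_gap: int = 800,
    edge_margin: int = 1_000,
    rrna_lengths: tuple[int, ...] = (1_500, 3_000),
    n_invasion_sites: int = 30,
) -> ToyReference:
    """Deterministic toy reference under ``seed``.

    Genes are non-overlapping with at least ``min_gap`` between them and
    ``edge_margin`` from contig ends, so every promoter window (TSS ± 500)
    and read fragment stays in bounds.  rRNA references are drawn
    independently of the genome (21-mer sharing is vanishingly unlikely).
    Copies of the TSO 3' tail are planted directly upstream of
    ``n_invasion_sites`` intra-genic, non-promoter positions; molecules
    starting at those sites are strand-invasion artefacts by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 11)))
    lengths = rng.integers(gene_length[0], gene_length[1] + 1, size=n_genes)
    budget = chrom_len - 2 * edge_margin - int(lengths.sum()) - min_gap * (n_genes - 1)
    if budget < 0:
        raise ValueError("chromosome too short for the requested gene set")
    extra = rng.multinomial(budget, np.ones(n_genes) / n_genes)

    genome = list(_random_seq(rng, chrom_len))
    genes: list[Gene] = []
    pos = edge_margin
    for i, (L, e) in enumerate(zip(lengths, extra)):
        start = pos + int(e)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(f"gene{i + 1:03d}", chrom_name, start, start + int(L), strand))
        pos = start + int(L) + min_gap

    tail = TSO_TAIL
    h = 500  # promoter halfwidth; sites are kept out of promoter windows
    sites: list[tuple[str, int, str]] = []
    candidates = rng.permutation(n_genes)
    for gi in candidates:
        if len(sites) >= n_invasion_sites:
            break
        g = genes[gi]
        if g.strand == "+":
            lo, hi = g.start + h + len(tail) + 10, g.end - 80
        else:
            lo, hi = g.start + 80, g.end - h - len(tail) - 10
        if hi <= lo:
            continue
        site = int(rng.integers(lo, hi))
        if g.strand == "+":
            genome[site - len(tail) : site] = list(tail)
        else:
            genome[site + 1 : site + 1 + len(tail)] = list(revcomp(tail))
        sites.append((g.gene_id, site, g.strand))

    rrna = {
        f"rRNA_{i + 1}": _random_seq(rng, L) for i, L in enumerate(rrna_lengths)
    }
    return ToyReference(
        genome={chrom_name: "".join(genome)},
        genes=genes,
        rrna=rrna,
        oligos={"adapter": ADAPTER, "rtp": RTP_CONST, "tso_tail": tail},
        invasion_sites=sites,
    )


@dataclass
class ResponseModel:
    """Condition → read-class probabilities, plus molecule-level knobs.

    Class logits are linear in log2-transformed levels; probabilities are
    their softmax.  Coefficients default to a surface that qualitatively
    mirrors the screened reaction: artefacts scale with log2(RTP/TSO)
    (strongest coefficient of any class, so artefacts strictly rise when
    RTP doubles at fixed TSO), rRNA shares a weaker diagonal and peaks at
    intermediate RNA mass, and the first-listed enzyme degrades faster at
    low RNA input.  Controls substitute small floor levels for the absent
    reagent, pushing them into the artefact-dominated regime.
    """

    intercepts: dict = field(
        default_factory=lambda: {
            "artefact": -2.2, "rrna": -1.6, "unmapped": -1.2,
            "genic": 1.1, "promoter": 0.9,
        }
    )
    #: coefficient on log2(rtp / tso)
    ratio_coefs: dict = field(
        default_factory=lambda: {"artefact": 0.9, "rrna": 0.35, "promoter": 0.15}
    )
    #: coefficient on log2(tso / 10)
    tso_coefs: dict = field(default_factory=lambda: {"genic": 0.25, "promoter": 0.3})
    #: quadratic penalty on log2(tso / 10) (saturation at extreme molarities)
    tso_quad: dict = field(default_factory=lambda: {"genic": -0.06, "promoter": -0.08})
    #: per-enzyme multiplier of the artefact low-RNA penalty max(0, log10(1000/rna))
    enzyme_lowrna: dict = field(default_factory=lambda: {"SSIII": 0.9, "SSIV": 0.3})
    #: rRNA mid-RNA bump: + coef * (2.5 - |log10(rna) - 2.5|)
    rrna_midrna: float = 0.25
    rtp_floor: float = 0.05   # μM stand-in for a no-RTP control
    rna_floor: float = 0.01   # pg stand-in for a no-RNA control
    si_fraction: float = 0.06       # fraction of genic/promoter molecules at invasion sites
    duplication_rate: float = 0.3   # chance a mapped read is a PCR duplicate
    depth_exponent: float = 0.35    # relative yield ~ (tso/10) ** exponent
    control_depth_factor: float = 0.05

    def class_probs(self, condition) -> np.ndarray:
        """Probability vector over CLASSES for one condition (controls use
        the floor levels for the absent reagent)."""
        tso = condition.tso if condition.tso is not None else self.rtp_floor
        rtp = condition.rtp if condition.rtp is not None else self.rtp_floor
        rna = condition.rna if condition.rna is not None else self.rna_floor
        if min(tso, rtp, rna) <= 0:
            raise ValueError("levels must be strictly positive")
        x_ratio = np.log2(rtp / tso)
        x_tso = np.log2(tso / 10.0)
        lowrna = max(0.0, np.log10(1000.0 / rna))
        enz = self.enzyme_lowrna.get(condition.enzyme, 0.5)
        logits = []
        for c in CLASSES:
            l = self.intercepts[c]
            l += self.ratio_coefs.get(c, 0.0) * x_ratio
            l += self.tso_coefs.get(c, 0.0) * x_tso
            l += self.tso_quad.get(c, 0.0) * x_tso**2
            if c == "artefact":
                l += enz * lowrna
            if c == "rrna":
                l += self.rrna_midrna * (2.5 - abs(np.log10(rna) - 2.5))
            logits.append(l)
        logits = np.array(logits)
        p = np.exp(logits - logits.max())
        return p / p.sum()

    def depth_factor(self, condition) -> float:
        """Relative sequence yield of a condition (arbitrary units, ~1 at
        the reference 10 μM TSO); controls yield a small fixed fraction."""
        if condition.is_control:
            return self.control_depth_factor
        return float((condition.tso / 10.0) ** self.depth_exponent)


def response_surface(model: ResponseModel, condition) -> np.ndarray:
    """Class probability vector of ``condition`` under ``model`` (ordered
    as CLASSES; sums to 1 by construction, smooth in log-levels)."""
    return model.class_probs(condition)


class ExactMatcher:
    """Exact-match placement of error-free reads on the toy genome.

    Indexes every genome k-mer (default k=20) and places a query at the
    first locus whose full-length sequence matches exactly, searching the
    forward then the reverse strand.  This is deliberately not an aligner —
    it exists so synthetic truth coordinates can be recovered from read
    sequences alone; real data should arrive as externally aligned records.
    """

    def __init__(self, genome: dict[str, str], k: int = 20):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((chrom, i))

    def _place(self, seq: str) -> tuple[str, int] | None:
        for chrom, i in self.index.get(seq[: self.k], ()):
            if self.genome[chrom][i : i + len(seq)] == seq:
                return chrom, i
        return None

    def align(self, seq: str) -> AlignmentMate | None:
        seq = seq.upper()
        if len(seq) < self.k:
            return None
        hit = self._place(seq)
        if hit is not None:
            return AlignmentMate(hit[0], hit[1], hit[1] + len(seq), "+")
        hit = self._place(revcomp(seq))
        if hit is not None:
            return AlignmentMate(hit[0], hit[1], hit[1] + len(seq), "-")
        return None


# ---------------------------------------------------------------------------
# read sampling

TRUTH_COLUMNS = [
    "plate_id", "well", "read_id", "cls", "gene_id", "si", "umi",
    "chrom", "m1_start", "m1_end", "m1_strand",
    "m2_start", "m2_end", "m2_strand",
]


def sample_well_reads(
    well,
    reference: ToyReference,
    model: ResponseModel,
    depth: int,
    seed: int,
    structure: ReadStructure = ReadStructure(),
    error_rate: float = 0.0,
):
    """Emit ``depth`` read pairs for one well plus their truth rows.

    ``well`` is a mapping with plate_id, well, barcode_seq, index_label and
    the condition columns (tso_uM, rtp_uM, rna_pg, enzyme).  Returns
    ``(reads, truth)`` where reads is a list of (read_id, r1, i1, r2) and
    truth a DataFrame with one row per pair.  Class counts are multinomial
    at the condition's response-surface probabilities; mapped classes carry
    head-to-head mate coordinates and UMI-level PCR duplication.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    from .design import Condition

    cond = Condition(
        tso=None if pd.isna(well["tso_uM"]) else float(well["tso_uM"]),
        rtp=None if pd.isna(well["rtp_uM"]) else float(well["rtp_uM"]),
        rna=None if pd.isna(well["rna_pg"]) else float(well["rna_pg"]),
        enzyme=str(well["enzyme"]),
    )
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 23)))
    probs = model.class_probs(cond)
    counts = rng.multinomial(depth, probs)

    chrom = next(iter(reference.genome))
    genome = reference.genome[chrom]
    barcode = str(well["barcode_seq"])
    index_seq = INDEX_SEQUENCES[str(well["index_label"])]
    insert_len = structure.read1_length - structure.insert_offset
    r2_len = structure.read2_length
    plate_id, well_id = str(well["plate_id"]), str(well["well"])

    sites_by_gene: dict[str, list[tuple[int, str]]] = {}
    for gid, pos, strand in reference.invasion_sites:
        sites_by_gene.setdefault(gid, []).append((pos, strand))
    all_sites = list(reference.invasion_sites)

    reads, truth = [], []
    serial = 0

    def emit(cls, insert, r2, gene_id=None, si=False, umi=None, m1=None, m2=None):
        nonlocal serial
        serial += 1
        rid = f"{plate_id}:{well_id}:{serial}"
        if umi is None:
            umi = _random_seq(rng, structure.umi_length)
        r1 = (barcode + umi + insert)[: structure.read1_length]
        r1 = r1.ljust(structure.read1_length, "A")
        if error_rate > 0:
            r1, i1s, r2 = (
                _mutate(rng, r1, error_rate),
                _mutate(rng, index_seq, error_rate),
                _mutate(rng, r2, error_rate),
            )
        else:
            i1s = index_seq
        reads.append((rid, r1, i1s, r2))
        truth.append(
            {
                "plate_id": plate_id, "well": well_id, "read_id": rid,
                "cls": cls, "gene_id": gene_id, "si": bool(si), "umi": umi,
                "chrom": chrom if m1 is not None else None,
                "m1_start": m1[0] if m1 else None,
                "m1_end": m1[1] if m1 else None,
                "m1_strand": m1[2] if m1 else None,
                "m2_start": m2[0] if m2 else None,
                "m2_end": m2[1] if m2 else None,
                "m2_strand": m2[2] if m2 else None,
            }
        )

    # --- unmapped-ish classes ------------------------------------------
    adapter, rtp_oligo = reference.oligos["adapter"], reference.oligos["rtp"]
    dimer = (rtp_oligo + revcomp(adapter) + rtp_oligo)
    for _ in range(int(counts[CLASSES.index("artefact")])):
        if rng.random() < 0.5:  # oligo-on-oligo product
            off = int(rng.integers(0, 5))
            insert = dimer[off : off + insert_len]
            r2 = revcomp(insert)[:r2_len]
        else:  # low-complexity product
            unit = ["A", "T", "AT", "GC", "CA"][int(rng.integers(0, 5))]
            insert = (unit * insert_len)[:insert_len]
            r2 = (unit * r2_len)[:r2_len]
        emit("artefact", insert, r2)

    rrna_names = list(reference.rrna)
    for _ in range(int(counts[CLASSES.index("rrna")])):
        ref = reference.rrna[rrna_names[int(rng.integers(0, len(rrna_names)))]]
        frag = int(rng.integers(insert_len + r2_len, insert_len + r2_len + 120))
        p = int(rng.integers(0, len(ref) - frag))
        emit("rrna", ref[p : p + insert_len], revcomp(ref[p + frag - r2_len : p + frag]))

    for _ in range(int(counts[CLASSES.index("unmapped")])):
        emit("unmapped", _random_seq(rng, insert_len), _random_seq(rng, r2_len))

    # --- mapped classes with PCR duplication ---------------------------
    genes = reference.genes
    h = 500

    def new_molecule(cls):
        if cls == "promoter":
            g = genes[int(rng.integers(0, len(genes)))]
            if g.strand == "+":
                pos = int(rng.integers(g.tss, g.tss + h))
            else:
                pos = int(rng.integers(g.tss - h + 1, g.tss + 1))
            si = False
        else:  # genic, outside promoter windows
            if all_sites and rng.random() < model.si_fraction:
                gid, pos, strand = all_sites[int(rng.integers(0, len(all_sites)))]
                g = next(x for x in genes if x.gene_id == gid)
                si = True
            else:
                si = False
                for _ in range(50):
                    g = genes[int(rng.integers(0, len(genes)))]
                    if g.strand == "+":
                        lo, hi = g.tss + h, g.end - 40
                    else:  # promoter window is half-open [tss-h, tss+h)
                        lo, hi = g.start + 40, g.tss - h
                    if hi > lo:
                        pos = int(rng.integers(lo, hi))
                        # avoid accidentally landing on a planted site
                        if all(abs(pos - s) > 2 for s, _ in sites_by_gene.get(g.gene_id, [])):
                            break
                else:
                    raise RuntimeError("could not place a genic read")
        frag = int(rng.integers(insert_len + r2_len + 20, 350))
        umi = _random_seq(rng, structure.umi_length)
        if g.strand == "+":
            m1 = (pos, pos + insert_len, "+")
            m2 = (pos + frag - r2_len, pos + frag, "-")
            insert = genome[pos : pos + insert_len]
            r2 = revcomp(genome[pos + frag - r2_len : pos + frag])
        else:
            m1 = (pos - insert_len + 1, pos + 1, "-")
            m2 = (pos - frag + 1, pos - frag + 1 + r2_len, "+")
            insert = revcomp(genome[pos - insert_len + 1 : pos + 1])
            r2 = genome[pos - frag + 1 : pos - frag + 1 + r2_len]
        return {
            "gene_id": g.gene_id, "si": si, "umi": umi,
            "insert": insert, "r2": r2, "m1": m1, "m2": m2,
        }

    for cls in ("genic", "promoter"):
        n_cls = int(counts[CLASSES.index(cls)])
        molecules: list[dict] = []
        for _ in range(n_cls):
            if molecules and rng.random() < model.duplication_rate:
                mol = molecules[int(rng.integers(0, len(molecules)))]
            else:
                mol = new_molecule(cls)
                molecules.append(mol)
            emit(cls, mol["insert"], mol["r2"], gene_id=mol["gene_id"],
                 si=mol["si"], umi=mol["umi"], m1=mol["m1"], m2=mol["m2"])

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = [truth[i] for i in order]
    return reads, pd.DataFrame(truth, columns=TRUTH_COLUMNS)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(out)
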