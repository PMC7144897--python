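"""Demultiplexing of multiplexed screen reads.

Each well of a pooled screen is identified by the combination of a barcode
(read from the first bases of read 1, carried on the template-switching
oligonucleotide) and a sequencing index (its own 8-nt read, one per plate
zone).  Demultiplexing maps the (index, barcode) pair to a well through the
plate layouts and extracts the UMI that follows the barcode on read 1.

Barcodes tolerate a configurable number of mismatches (default 1; the
default pools keep pairwise Hamming distance >= 3 so distance-1 correction
is unambiguous); indexes are matched exactly by default.  Reads whose
nearest barcode is tied between two entries are counted ``ambiguous``
rather than assigned.
"""

from __future__ import annotations

import gzip
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .design import BarcodePool

__all__ = [
    "ReadStructure",
    "DemuxRecord",
    "DemuxResult",
    "INDEX_SEQUENCES",
    "index_sequence",
    "match_barcode",
    "demultiplex",
    "read_fastq",
    "write_fastq",
]


@dataclass(frozen=True)
class ReadStructure:
    """Positions of the barcode and UMI in read 1 and the index length."""

    barcode_offset: int = 0
    barcode_length: int = 6
    umi_offset: int = 6
    umi_length: int = 8
    index_length: int = 8
    read1_length: int = 46
    read2_length: int = 21

    def __post_init__(self) -> None:
        b0, b1 = self.barcode_offset, self.barcode_offset + self.barcode_length
        u0, u1 = self.umi_offset, self.umi_offset + self.umi_length
        if max(b1, u1) > self.read1_length:
            raise ValueError("barcode/UMI spans exceed read-1 length")
        if not (b1 <= u0 or u1 <= b0):
            raise ValueError("barcode and UMI spans overlap")

    @property
    def insert_offset(self) -> int:
        return max(self.barcode_offset + self.barcode_length,
                   self.umi_offset + self.umi_length)

    def barcode(self, r1: str) -> str:
        return r1[self.barcode_offset : self.barcode_offset + self.barcode_length]

    def umi(self, r1: str) -> str:
        return r1[self.umi_offset : self.umi_offset + self.umi_length]

    def insert(self, r1: str) -> str:
        return r1[self.insert_offset :]


# Registry of 24 synthetic 8-nt index sequences (pairwise Hamming >= 3),
# labelled idx01..idx24: four replicate plates x six zones per enzyme, the
# same series reused across the two per-enzyme sequencing pools.
INDEX_SEQUENCES: dict[str, str] = {
    f"idx{i + 1:02d}": seq
    for i, (_, seq) in enumerate(
        sorted(BarcodePool.random_pool(size=24, length=8, min_distance=3, seed=7).entries.items())
    )
}


def index_sequence(label: str) -> str:
    return INDEX_SEQUENCES[label]


_SEQ_TO_INDEX = {s: l for l, s in INDEX_SEQUENCES.items()}


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _match(observed: str, table: dict[str, str], max_mismatch: int) -> tuple[str, str | None]:
    """('ok', id) | ('ambiguous', None) | ('none', None)."""
    best_d, best_id, tie = max_mismatch + 1, None, False
    for bid, seq in table.items():
        d = _hamming(observed, seq)
        if d < best_d:
            best_d, best_id, tie = d, bid, False
            if d == 0:
                break
        elif d == best_d:
            tie = True
    if best_id is None or best_d > max_mismatch:
        return "none", None
    if tie:
        return "ambiguous", None
    return "ok", best_id


def match_barcode(observed: str, table: dict[str, str], max_mismatch: int = 1) -> str | None:
    """Unique table entry within Hamming distance ``max_mismatch`` of
    ``observed``, or None on no hit or a distance tie."""
    status, bid = _match(observed, table, max_mismatch)
    return bid if status == "ok" else None


@dataclass
class DemuxRecord:
    read_id: str
    umi: str
    insert: str  # read-1 template after barcode + UMI
    r2: str


@dataclass
class DemuxResult:
    per_well: dict[tuple[str, str], list[DemuxRecord]] = field(default_factory=dict)
    unmatched: list[str] = field(default_factory=list)  # read ids
    counts: Counter = field(default_factory=Counter)    # assigned/ambiguous/unmatched

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"plate_id": p, "well": w, "n_pairs": len(recs)}
            for (p, w), recs in sorted(self.per_well.items())
        ]
        return pd.DataFrame(rows, columns=["plate_id", "well", "n_pairs"])


def build_demux_key(layouts: pd.DataFrame | list) -> dict[tuple[str, str], tuple[str, str]]:
    """(index_label, barcode_id) -> (plate_id, well) from one or more layout
    tables; raises on a key collision (the design guarantees none within a
    pool)."""
    if not isinstance(layouts, pd.DataFrame):
        frames = [l if isinstance(l, pd.DataFrame) else l.to_frame() for l in layouts]
        layouts = pd.concat(frames, ignore_index=True)
    key: dict[tuple[str, str], tuple[str, str]] = {}
    for _, r in layouts.iterrows():
        k = (str(r["index_label"]), str(r["barcode_id"]))
        if k in key:
            raise ValueError(f"demultiplexing key collision: {k}")
        key[k] = (str(r["plate_id"]), str(r["well"]))
    return key


def demultiplex(
    reads,
    layouts,
    structure: ReadStructure = ReadStructure(),
    max_mismatch_barcode: int = 1,
    max_mismatch_index: int = 0,
    barcode_table: dict[str, str] | None = None,
) -> DemuxResult:
    """Assign read pairs to wells by their (index, barcode) combination.

    ``reads`` iterates (read_id, r1, i1, r2) tuples.  ``layouts`` is a
    layout table (or list of tables / PlateLayout objects) providing
    barcode_id, barcode_seq, index_label and well per plate.  Reads with an
    unknown index or barcode go to ``unmatched``; barcode-distance ties are
    ``ambiguous``.  assigned + ambiguous + unmatched = total input pairs.
    """
    if not isinstance(layouts, pd.DataFrame):
        frames = [l if isinstance(l, pd.DataFrame) else l.to_frame() for l in layouts]
        layouts_df = pd.concat(frames, ignore_index=True)
    else:
        layouts_df = layouts
    key = build_demux_key(layouts_df)
    if barcode_table is None:
        barcode_table = {
            str(r["barcode_id"]): str(r["barcode_seq"])
            for _, r in layouts_df.drop_duplicates("barcode_id").iterrows()
        }
    index_table = {
        lbl: INDEX_SEQUENCES[lbl]
        for lbl in layouts_df["index_label"].astype(str).unique()
    }

    exact_bc = {s: b for b, s in barcode_table.items()}
    exact_idx = {s: l for l, s in index_table.items()}

    result = DemuxResult()
    per_well = defaultdict(list)
    for read_id, r1, i1, r2 in reads:
        obs_idx = i1[: structure.index_length]
        idx_label = exact_idx.get(obs_idx)
        if idx_label is None and max_mismatch_index > 0:
            status, idx_label = _match(obs_idx, index_table, max_mismatch_index)
            if status != "ok":
                idx_label = None
        obs_bc = structure.barcode(r1)
        bid = exact_bc.get(obs_bc)
        bc_status = "ok" if bid is not None else None
        if bc_status is None:
            bc_status, bid = _match(obs_bc, barcode_table, max_mismatch_barcode)
        if idx_label is None or bc_status == "none":
            result.counts["unmatched"] += 1
            result.unmatched.append(read_id)
            continue
        if bc_status == "ambiguous":
            result.counts["ambiguous"] += 1
            continue
        dest = key.get((idx_label, bid))
        if dest is None:
            result.counts["unmatched"] += 1
            result.unmatched.append(read_id)
            continue
        per_well[dest].append(
            DemuxRecord(read_id, structure.umi(r1), structure.insert(r1), r2)
        )
        result.counts["assigned"] += 1
    result.per_well = dict(per_well)
    return result


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path):
    """Yield (read_id, sequence) from a (optionally gzipped) FASTQ file."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence


def write_fastq(path, records) -> None:
    """Write (read_id, sequence) pairs as FASTQ with uniform quality."""
    with _open(path, "wt") as fh:
        for read_id, seq in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def paired_fastq_reader(r1_path, i1_path, r2_path):
    """Yield (read_id, r1, i1, r2) from three parallel FASTQ files."""
    for (rid1, r1), (rid2, i1), (rid3, r2) in zip(
        read_fastq(r1_path), read_fastq(i1_path), read_fastq(r2_path)
    ):
        if not (rid1 == rid2 == rid3):
            raise ValueError(f"FASTQ files out of sync at {rid1}/{rid2}/{rid3}")
        yield rid1, r1, i1, r2
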