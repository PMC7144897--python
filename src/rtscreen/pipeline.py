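"""End-to-end orchestration: simulate a screen, demultiplex, run QC,
and derive truth-table expectations for validation.

Each per-enzyme sequencing pool (up to four plates sharing one index
series) is demultiplexed separately, mirroring the one-run-per-enzyme
design in which index sequences are reused between enzymes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import qc as qcm
from .demux import DemuxResult, ReadStructure, demultiplex
from .design import PlateLayout
from .qc import QCParams, compute_qc_report, hurlbert_richness
from .synthdata import ExactMatcher, ResponseModel, ToyReference, sample_well_reads

__all__ = [
    "simulate_screen_reads",
    "qc_screen",
    "truth_well_metrics",
    "run_synthetic_screen",
]


def _well_seed(master_seed: int, plate_ix: int, well_ix: int) -> int:
    return int(
        np.random.SeedSequence((int(master_seed), 37, plate_ix, well_ix))
        .generate_state(1)[0] % (2**31)
    )


def simulate_screen_reads(
    layouts: list[PlateLayout],
    reference: ToyReference,
    model: ResponseModel,
    depth: int,
    seed: int,
    structure: ReadStructure = ReadStructure(),
    scale_depth: bool = True,
    error_rate: float = 0.0,
):
    """Reads and truth for every well of every layout.

    With ``scale_depth`` the nominal per-well ``depth`` is multiplied by the
    condition's relative-yield factor (so sequence yields correlate with
    TSO molarity, as in a real pool); otherwise every well gets exactly
    ``depth`` pairs.  Returns ``(reads, truth)`` with reads a flat list of
    (read_id, r1, i1, r2).
    """
    all_reads, truths = [], []
    for plate_ix, layout in enumerate(layouts):
        frame = layout.to_frame()
        for well_ix, row in frame.iterrows():
            cond = layout.condition(row["well"])
            d = depth
            if scale_depth:
                d = max(1, int(round(depth * model.depth_factor(cond))))
            reads, truth = sample_well_reads(
                row, reference, model, d,
                seed=_well_seed(seed, plate_ix, int(well_ix)),
                structure=structure, error_rate=error_rate,
            )
            all_reads.extend(reads)
            truths.append(truth)
    # control wells can yield all-NA coordinate columns; keep concat quiet
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        truth_df = pd.concat(truths, ignore_index=True)
    return all_reads, truth_df


def qc_screen(
    demux_result: DemuxResult,
    reference: ToyReference,
    params: QCParams = QCParams(),
    aligner: ExactMatcher | None = None,
    alignments=None,
) -> pd.DataFrame:
    """QC report table, one row per well with demultiplexed reads."""
    annotation = reference.annotation()
    if aligner is None and alignments is None:
        aligner = ExactMatcher(reference.genome)
    art = qcm.ArtefactClassifier(
        annotation.oligos, params.artefact_k, params.artefact_entropy_threshold
    )
    rib = qcm.RrnaClassifier(annotation.rrna_refs, params.rrna_k)
    rows = []
    for (plate_id, well), records in sorted(demux_result.per_well.items()):
        rep = compute_qc_report(
            plate_id, well, records, annotation, reference.genome,
            aligner=aligner, alignments=alignments, params=params,
            _artefact=art, _rrna=rib,
        )
        rows.append(rep.as_dict())
    return pd.DataFrame(rows)


def truth_well_metrics(truth: pd.DataFrame, rarefy_depth: int = 10) -> pd.DataFrame:
    """Per-well metric expectations straight from the generator truth table.

    Uses the same definitions as the QC cascade: artefact/rRNA/mapping over
    all pairs, promoter over mapped pairs, strand invasion over distinct
    (5' position, strand, UMI) molecules, richness on mapped reads per gene.
    """
    rows = []
    for (plate_id, well), grp in truth.groupby(["plate_id", "well"]):
        n = len(grp)
        mapped = grp[grp["cls"].isin(["genic", "promoter"])]
        five_prime = np.where(
            mapped["m1_strand"] == "+", mapped["m1_start"], mapped["m1_end"] - 1
        )
        mol = pd.DataFrame(
            {"pos": five_prime, "strand": mapped["m1_strand"],
             "umi": mapped["umi"], "si": mapped["si"]}
        ).drop_duplicates(["pos", "strand", "umi"])
        gene_counts = mapped["gene_id"].value_counts()
        rows.append(
            {
                "plate_id": plate_id,
                "well": well,
                "extracted_pairs": n,
                "artefact_pct": 100.0 * (grp["cls"] == "artefact").mean(),
                "rrna_pct": 100.0 * (grp["cls"] == "rrna").mean(),
                "mapping_pct": 100.0 * len(mapped) / n,
                "promoter_pct": (
                    100.0 * (mapped["cls"] == "promoter").mean() if len(mapped) else None
                ),
                "strand_invasion_pct": (
                    100.0 * mol["si"].mean() if len(mol) else None
                ),
                "richness_at_10": hurlbert_richness(gene_counts.to_dict(), rarefy_depth),
                "n_properly_mapped": len(mapped),
                "n_molecules": len(mol),
            }
        )
    return pd.DataFrame(rows)


def run_synthetic_screen(
    layouts: list[PlateLayout],
    reference: ToyReference,
    model: ResponseModel,
    depth: int,
    seed: int,
    params: QCParams = QCParams(),
    structure: ReadStructure = ReadStructure(),
    scale_depth: bool = True,
    error_rate: float = 0.0,
):
    """Simulate → demultiplex → QC for one per-enzyme pool of layouts.

    Returns ``(qc_table, truth_table, demux_result)``.
    """
    reads, truth = simulate_screen_reads(
        layouts, reference, model, depth, seed,
        structure=structure, scale_depth=scale_depth, error_rate=error_rate,
    )
    demux_result = demultiplex(reads, [l.to_frame() for l in layouts], structure)
    qc_table = qc_screen(demux_result, reference, params)
    return qc_table, truth, demux_result
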