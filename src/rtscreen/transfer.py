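"""Acoustic-droplet transfer programs for randomized RT plates.

Converts a :class:`~rtscreen.design.PlateLayout` into an ordered list of
25-nl-quantized droplet transfers from a source plate to the 384-well
destination plate (500 nl per reaction), simulates the instrument run
against source-well volume balances, and verifies that the executed event
log reconstructs the design — closing the design → execution loop.

Source organization: every concentration level of TSO/RTP/RNA gets its own
pre-dilution well whose stock is chosen so that a fixed per-reagent
transfer volume hits the target final concentration exactly (TSO stocks are
additionally per-barcode, since the barcode is carried on the
oligonucleotide).  This keeps droplet quantization exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .design import ALL_WELLS, PlateLayout, well_name

__all__ = [
    "ReagentKey",
    "SourceWell",
    "SourcePlan",
    "TransferStep",
    "TransferSheet",
    "Event",
    "EventLog",
    "WellComposition",
    "TransferError",
    "QuantizationError",
    "OverCommitmentError",
    "default_source_plan",
    "compute_well_recipe",
    "build_transfer_sheet",
    "simulate_run",
    "verify_round_trip",
]

DROPLET_NL = 25
TOTAL_VOLUME_NL = 500

#: conventional reagent-major transfer order (mastermix first, water last)
REAGENT_ORDER = ("mastermix", "tso", "rtp", "rna", "water")

# fixed per-reagent transfer volumes (nl); water fills the remainder
DEFAULT_VOLUMES = {"mastermix": 150, "tso": 100, "rtp": 100, "rna": 100}


class TransferError(ValueError):
    pass


class QuantizationError(TransferError):
    """A target level is not reachable by an integer droplet count."""


class OverCommitmentError(TransferError):
    """Per-reagent volumes exceed the total reaction volume."""


#: (kind, qualifier, level) — e.g. ("tso", "BC07", 160.0), ("rtp", "", 4.0),
#: ("rna", "", 1000.0), ("mastermix", "", 0.0), ("water", "", 0.0)
ReagentKey = tuple[str, str, float]


@dataclass
class SourceWell:
    plate: str
    well: str
    key: ReagentKey
    stock: float          # μM for tso/rtp, pg/nl for rna, 0 for mastermix/water
    volume_nl: float
    dead_volume_nl: float

    @property
    def available_nl(self) -> float:
        return self.volume_nl - self.dead_volume_nl


@dataclass
class SourcePlan:
    """Map of reagent keys to stocked source wells."""

    wells: dict[ReagentKey, SourceWell] = field(default_factory=dict)

    def by_location(self) -> dict[tuple[str, str], SourceWell]:
        return {(sw.plate, sw.well): sw for sw in self.wells.values()}

    def lookup(self, key: ReagentKey) -> SourceWell:
        try:
            return self.wells[key]
        except KeyError:
            raise QuantizationError(
                f"no source dilution for reagent {key[0]!r} "
                f"{'barcode ' + key[1] + ' ' if key[1] else ''}level {key[2]}"
            ) from None


def default_source_plan(
    layout: PlateLayout,
    total_volume: int = TOTAL_VOLUME_NL,
    volumes: dict[str, int] | None = None,
    initial_volume_nl: float = 20_000,
    dead_volume_nl: float = 2_500,
    capacity_nl: float = 65_000,
) -> SourcePlan:
    """Source plan serving one plate, with per-level pre-dilutions.

    Stocks satisfy ``stock × v / total = level`` (resp. ``stock × v = mass``
    for RNA) at the fixed per-reagent volume ``v``, so every recipe volume
    is an exact droplet multiple.  High-demand wells (mastermix, water) are
    seeded with enough volume for 384 reactions plus dead volume, capped at
    the plate capacity.
    """
    if volumes is None:
        volumes = dict(DEFAULT_VOLUMES)
    for kind, v in volumes.items():
        if v % DROPLET_NL != 0:
            raise QuantizationError(f"fixed {kind} volume {v} nl is not a droplet multiple")

    plan = SourcePlan()
    coords = _coordinate_allocator()

    def add(key: ReagentKey, stock: float, need_nl: float) -> None:
        vol = min(capacity_nl, max(initial_volume_nl, need_nl + dead_volume_nl))
        plate, well = next(coords)
        plan.wells[key] = SourceWell(plate, well, key, stock, vol, dead_volume_nl)

    n_wells = len(layout.wells)
    add(("mastermix", "", 0.0), 0.0, n_wells * volumes["mastermix"])

    tso_levels = sorted(
        {c.tso for c, _ in layout.wells.values() if c.tso is not None}
    )
    barcodes = sorted(set(layout.barcodes.values()))
    if not barcodes:
        raise TransferError("layout has no barcodes; run assign_barcodes first")
    for bc in barcodes:
        for lvl in tso_levels:
            add(("tso", bc, lvl), lvl * total_volume / volumes["tso"], 0.0)
    for lvl in sorted({c.rtp for c, _ in layout.wells.values() if c.rtp is not None}):
        add(("rtp", "", lvl), lvl * total_volume / volumes["rtp"], 0.0)
    for lvl in sorted({c.rna for c, _ in layout.wells.values() if c.rna is not None}):
        add(("rna", "", lvl), lvl / volumes["rna"], 0.0)
    add(("water", "", 0.0), 0.0, n_wells * total_volume)  # generous upper bound
    return plan


def _coordinate_allocator():
    """Yield (plate, well) coordinates across Source_1, Source_2, ... plates."""
    plate_no = 0
    while True:
        plate_no += 1
        for r in range(16):
            for c in range(24):
                yield f"Source_{plate_no}", well_name(r, c)


@dataclass(frozen=True)
class TransferStep:
    source_plate: str
    source_well: str
    dest_plate: str
    dest_well: str
    volume_nl: int

    def __post_init__(self) -> None:
        if self.volume_nl <= 0 or self.volume_nl % DROPLET_NL != 0:
            raise QuantizationError(
                f"transfer volume {self.volume_nl} nl is not a positive "
                f"multiple of the {DROPLET_NL} nl droplet"
            )


@dataclass
class TransferSheet:
    steps: list[TransferStep]

    def __len__(self) -> int:
        return len(self.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "Source Plate Name": s.source_plate,
                    "Source Well": s.source_well,
                    "Destination Plate Name": s.dest_plate,
                    "Destination Well": s.dest_well,
                    "Transfer Volume": s.volume_nl,
                }
                for s in self.steps
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TransferSheet":
        df = pd.read_csv(path)
        return cls(
            [
                TransferStep(
                    r["Source Plate Name"], r["Source Well"],
                    r["Destination Plate Name"], r["Destination Well"],
                    int(r["Transfer Volume"]),
                )
                for _, r in df.iterrows()
            ]
        )


def _quantize(v: float) -> int:
    """Exact droplet multiple or QuantizationError."""
    n = v / DROPLET_NL
    if abs(n - round(n)) > 1e-6 or round(n) <= 0:
        raise QuantizationError(f"required volume {v:g} nl is not a multiple of {DROPLET_NL} nl")
    return int(round(n)) * DROPLET_NL


def compute_well_recipe(
    condition,
    barcode_id: str,
    source_plan: SourcePlan,
    dest_plate: str,
    dest_well: str,
    total_volume: int = TOTAL_VOLUME_NL,
    volumes: dict[str, int] | None = None,
) -> list[TransferStep]:
    """Per-well droplet recipe: mastermix, TSO, RTP, RNA, then water to
    ``total_volume``.  Controls omit the absent reagent, its volume absorbed
    by the water top-up.  Reagent volumes derive from the source stocks
    (``stock × v / total = level``) and must land on exact droplet multiples.
    """
    if volumes is None:
        volumes = dict(DEFAULT_VOLUMES)
    steps: list[TransferStep] = []
    delivered = 0

    def emit(key: ReagentKey, vol: float) -> None:
        nonlocal delivered
        sw = source_plan.lookup(key)
        q = _quantize(vol)
        steps.append(TransferStep(sw.plate, sw.well, dest_plate, dest_well, q))
        delivered += q

    emit(("mastermix", "", 0.0), volumes["mastermix"])
    if condition.tso is not None:
        sw = source_plan.lookup(("tso", barcode_id, condition.tso))
        emit(("tso", barcode_id, condition.tso), condition.tso * total_volume / sw.stock)
    if condition.rtp is not None:
        sw = source_plan.lookup(("rtp", "", condition.rtp))
        emit(("rtp", "", condition.rtp), condition.rtp * total_volume / sw.stock)
    if condition.rna is not None:
        sw = source_plan.lookup(("rna", "", condition.rna))
        emit(("rna", "", condition.rna), condition.rna / sw.stock)

    water = total_volume - delivered
    if water < 0:
        raise OverCommitmentError(
            f"{dest_well}: reagent volumes ({delivered} nl) exceed the "
            f"{total_volume} nl reaction"
        )
    if water > 0:
        emit(("water", "", 0.0), water)
    return steps


def build_transfer_sheet(
    layout: PlateLayout,
    source_plan: SourcePlan,
    dest_plate: str | None = None,
    total_volume: int = TOTAL_VOLUME_NL,
) -> TransferSheet:
    """All 384 well recipes, ordered reagent-major (mastermix block first,
    water last) and destination-row-major within each reagent block."""
    if dest_plate is None:
        dest_plate = layout.plate_id
    per_well: dict[str, list[TransferStep]] = {}
    errors = []
    for w in ALL_WELLS:
        cond, _ = layout.wells[w]
        try:
            per_well[w] = compute_well_recipe(
                cond, layout.barcodes[w], source_plan, dest_plate, w, total_volume
            )
        except TransferError as e:
            errors.append(f"{w}: {e}")
    if errors:
        raise TransferError("recipe failures: " + "; ".join(errors))

    loc = source_plan.by_location()
    kind_rank = {k: i for i, k in enumerate(REAGENT_ORDER)}
    well_rank = {w: i for i, w in enumerate(ALL_WELLS)}
    steps = [s for w in ALL_WELLS for s in per_well[w]]
    steps.sort(
        key=lambda s: (kind_rank[loc[(s.source_plate, s.source_well)].key[0]],
                       well_rank[s.dest_well])
    )
    return TransferSheet(steps)


@dataclass
class Event:
    step_index: int
    step: TransferStep
    reagent: ReagentKey
    stock: float
    balance_before: float
    balance_after: float
    status: str  # "ok" | "insufficient"


@dataclass
class EventLog:
    events: list[Event]

    def executed(self) -> list[Event]:
        return [e for e in self.events if e.status == "ok"]

    def flagged(self) -> list[Event]:
        return [e for e in self.events if e.status != "ok"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": e.step_index,
                    "source_plate": e.step.source_plate,
                    "source_well": e.step.source_well,
                    "dest_well": e.step.dest_well,
                    "volume_nl": e.step.volume_nl,
                    "reagent": e.reagent[0],
                    "qualifier": e.reagent[1],
                    "level": e.reagent[2],
                    "stock": e.stock,
                    "balance_before": e.balance_before,
                    "balance_after": e.balance_after,
                    "status": e.status,
                }
                for e in self.events
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class WellComposition:
    """Final state of one destination well after a simulated run."""

    total_nl: float = 0.0
    tso_uM: float | None = None
    rtp_uM: float | None = None
    rna_pg: float | None = None
    barcode_id: str | None = None


def simulate_run(
    sheet: TransferSheet,
    source_plan: SourcePlan,
    strict: str = "skip",
    total_volume: int = TOTAL_VOLUME_NL,
) -> tuple[EventLog, dict[str, WellComposition]]:
    """Execute the sheet against source balances.

    Debits each source well sequentially; a step that would push a source
    below its dead volume is flagged ``insufficient`` and, per ``strict``,
    either skipped (``"skip"``) or aborts the remaining run (``"halt"``).
    Returns the event log and each destination well's final composition
    (concentrations recomputed from the executed volumes and stocks).
    """
    if strict not in ("skip", "halt"):
        raise ValueError("strict must be 'skip' or 'halt'")
    loc = source_plan.by_location()
    balances = {k: sw.volume_nl for k, sw in loc.items()}
    events: list[Event] = []
    halted = False
    for i, step in enumerate(sheet.steps):
        sw = loc[(step.source_plate, step.source_well)]
        bal = balances[(step.source_plate, step.source_well)]
        if halted:
            break
        if bal - step.volume_nl < sw.dead_volume_nl:
            events.append(Event(i, step, sw.key, sw.stock, bal, bal, "insufficient"))
            if strict == "halt":
                halted = True
            continue
        balances[(step.source_plate, step.source_well)] = bal - step.volume_nl
        events.append(
            Event(i, step, sw.key, sw.stock, bal, bal - step.volume_nl, "ok")
        )
    log = EventLog(events)

    comp: dict[str, WellComposition] = {}
    # first pass: delivered totals
    for e in log.executed():
        comp.setdefault(e.step.dest_well, WellComposition()).total_nl += e.step.volume_nl
    for e in log.executed():
        c = comp[e.step.dest_well]
        kind = e.reagent[0]
        amount = e.stock * e.step.volume_nl
        if kind == "tso":
            c.tso_uM = (c.tso_uM or 0.0) + amount / c.total_nl
            c.barcode_id = e.reagent[1]
        elif kind == "rtp":
            c.rtp_uM = (c.rtp_uM or 0.0) + amount / c.total_nl
        elif kind == "rna":
            c.rna_pg = (c.rna_pg or 0.0) + amount  # stock is pg/nl → mass
    return log, comp


def verify_round_trip(
    event_log: EventLog,
    layout: PlateLayout,
    rel_tol: float = 1e-9,
) -> pd.DataFrame:
    """Reconstruct each well's (TSO, RTP, RNA, barcode) from the executed
    event log and compare with the design.  Returns a mismatch report —
    empty when the log faithfully realizes the layout."""
    comp: dict[str, WellComposition] = {}
    for e in event_log.executed():
        c = comp.setdefault(e.step.dest_well, WellComposition())
        c.total_nl += e.step.volume_nl
    for e in event_log.executed():
        c = comp[e.step.dest_well]
        kind = e.reagent[0]
        if kind == "tso":
            c.tso_uM = (c.tso_uM or 0.0) + e.stock * e.step.volume_nl / TOTAL_VOLUME_NL
            c.barcode_id = e.reagent[1]
        elif kind == "rtp":
            c.rtp_uM = (c.rtp_uM or 0.0) + e.stock * e.step.volume_nl / TOTAL_VOLUME_NL
        elif kind == "rna":
            c.rna_pg = (c.rna_pg or 0.0) + e.stock * e.step.volume_nl

    def close(a: float | None, b: float | None) -> bool:
        if a is None or b is None:
            return a is None and b is None
        return abs(a - b) <= rel_tol * max(abs(a), abs(b), 1.0)

    rows = []
    for w in ALL_WELLS:
        cond, _ = layout.wells[w]
        expect_bc = layout.barcodes.get(w)
        c = comp.get(w)
        if c is None:
            rows.append({"well": w, "field": "all", "expected": "present", "observed": "missing"})
            continue
        checks = [
            ("tso_uM", cond.tso, c.tso_uM),
            ("rtp_uM", cond.rtp, c.rtp_uM),
            ("rna_pg", cond.rna, c.rna_pg),
            ("total_nl", float(TOTAL_VOLUME_NL), c.total_nl),
        ]
        for name, exp, obs in checks:
            if not close(exp, obs):
                rows.append({"well": w, "field": name, "expected": exp, "observed": obs})
        if cond.tso is not None and c.barcode_id != expect_bc:
            rows.append({"well": w, "field": "barcode", "expected": expect_bc, "observed": c.barcode_id})
    return pd.DataFrame(rows, columns=["well", "field", "expected", "observed"])
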