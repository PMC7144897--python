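"""Factorial design, plate zoning and seeded randomization for RT parameter screens.

A screen explores a 4-D grid — template-switching oligonucleotide (TSO)
molarity, reverse-transcription primer (RTP) molarity, RNA input mass and
enzyme — on 384-well plates.  Each plate is split into six interleaved
64-well *zones*, one per RNA mass; a zone holds the full TSO×RTP grid once
(54 experimental wells with the default series) plus nine no-RTP controls
(one per TSO level) and one no-RNA control.  Zone contents are pooled into
one indexed PCR, and wells within a zone are told apart by barcodes carried
on the TSO, so the (index, barcode) pair is a collision-free demultiplexing
key by construction.

Well positions and barcode assignments are randomized with a single master
seed per plate; sub-streams for the two randomization stages are derived by
fixed labeled splits so that adding a stage never perturbs another stage's
draw, and the same seed always reproduces a bit-identical layout.  The
positions of the 60 controls on a plate form an identifying fingerprint of
the randomization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorLevels",
    "Condition",
    "ControlRules",
    "ZonePlan",
    "PlateLayout",
    "BarcodePool",
    "enumerate_conditions",
    "build_zone_plans",
    "randomize_layout",
    "assign_barcodes",
    "layout_fingerprint",
    "build_replicate_layouts",
    "pcr_cycles",
    "default_interleaving",
    "well_name",
    "ALL_WELLS",
    "DesignError",
    "CapacityError",
]

ROWS = "ABCDEFGHIJKLMNOP"
N_COLS = 24
PLATE_SIZE = 384

# sub-stream labels for the per-plate master seed (fixed; order-independent)
_STAGE_PERMUTE = 1
_STAGE_BARCODE = 2


class DesignError(ValueError):
    """Invalid screen configuration."""


class CapacityError(DesignError):
    """Requested grid does not fit the zone size."""


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> 'A1'..'P24'."""
    return f"{ROWS[row]}{col + 1}"


#: all 384 well coordinates in row-major canonical order
ALL_WELLS = tuple(well_name(r, c) for r in range(16) for c in range(N_COLS))


@dataclass(frozen=True)
class FactorLevels:
    """Ordered level series of the four screened factors.

    Defaults follow the high-dynamic-range screen: nine TSO levels on a
    2-fold series from 0.625 to 160 μM, six RTP levels from 1 to 24 μM,
    six RNA masses on a 10-fold series from 1 pg to 100 ng, and the
    SuperScript III / IV enzyme pair.
    """

    tso_molarities: tuple[float, ...] = (0.625, 1.25, 2.5, 5, 10, 20, 40, 80, 160)
    rtp_molarities: tuple[float, ...] = (1, 2, 4, 8, 16, 24)
    rna_masses: tuple[float, ...] = (1, 10, 100, 1_000, 10_000, 100_000)
    enzymes: tuple[str, ...] = ("SSIII", "SSIV")

    def __post_init__(self) -> None:
        for name in ("tso_molarities", "rtp_molarities", "rna_masses"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise DesignError(f"{name}: empty level list")
            if any(v <= 0 for v in vals):
                raise DesignError(f"{name}: levels must be strictly positive")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise DesignError(f"{name}: levels must be strictly increasing")
        if len(self.enzymes) == 0:
            raise DesignError("enzymes: empty level list")
        if len(set(self.enzymes)) != len(self.enzymes):
            raise DesignError("enzymes: duplicate labels")


@dataclass(frozen=True)
class Condition:
    """One point of the parameter grid, or a negative control.

    ``rtp is None`` marks a no-RTP control, ``rna is None`` a no-RNA
    control; experimental wells have all three levels set.
    """

    tso: float | None
    rtp: float | None
    rna: float | None
    enzyme: str

    def __post_init__(self) -> None:
        if self.rtp is None and self.rna is None:
            raise DesignError("a control omits either RTP or RNA, not both")

    @property
    def is_control(self) -> bool:
        return self.rtp is None or self.rna is None

    @property
    def control_type(self) -> str:
        if self.rtp is None:
            return "no_rtp"
        if self.rna is None:
            return "no_rna"
        return "none"


@dataclass(frozen=True)
class ControlRules:
    """Per-zone negative controls: one no-RTP control per TSO level and a
    single no-RNA well at the median TSO/RTP levels of the series."""

    no_rtp_per_tso_level: bool = True
    n_no_rna: int = 1


@dataclass
class ZonePlan:
    zone_id: int
    rna_mass: float
    members: list[Condition]
    index_label: str | None = None

    @property
    def n_no_rtp(self) -> int:
        return sum(1 for m in self.members if m.control_type == "no_rtp")

    @property
    def n_no_rna(self) -> int:
        return sum(1 for m in self.members if m.control_type == "no_rna")


@dataclass
class BarcodePool:
    """Named DNA barcodes carried on the template-switching oligonucleotide."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        seqs = list(self.entries.values())
        if not seqs:
            raise DesignError("empty barcode pool")
        if len({len(s) for s in seqs}) != 1:
            raise DesignError("barcode sequences must share one length")
        if len(set(seqs)) != len(seqs):
            raise DesignError("barcode sequences must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.entries.values())))

    @classmethod
    def random_pool(
        cls,
        size: int = 70,
        length: int = 6,
        min_distance: int = 3,
        seed: int = 0,
    ) -> "BarcodePool":
        """Draw ``size`` barcodes of ``length`` nt with pairwise Hamming
        distance >= ``min_distance`` (rejection sampling, deterministic
        under ``seed``).  Distance 3 makes single-mismatch correction
        unambiguous."""
        rng = np.random.default_rng(np.random.SeedSequence((seed, 97)))
        chosen: list[str] = []
        bases = np.array(list("ACGT"))
        attempts = 0
        while len(chosen) < size:
            attempts += 1
            if attempts > 200_000:
                raise DesignError(
                    f"cannot find {size} barcodes of length {length} "
                    f"at distance {min_distance}"
                )
            cand = "".join(rng.choice(bases, size=length))
            if all(_hamming(cand, s) >= min_distance for s in chosen):
                chosen.append(cand)
        return cls({f"BC{i + 1:02d}": s for i, s in enumerate(chosen)})


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class PlateLayout:
    """Randomized assignment of conditions, barcodes and zones to 384 wells."""

    plate_id: str
    enzyme: str
    replicate_index: int
    seed: int
    # well coordinate -> (condition, zone_id); barcodes filled by assign_barcodes
    wells: dict[str, tuple[Condition, int]] = field(default_factory=dict)
    barcodes: dict[str, str] = field(default_factory=dict)  # well -> barcode_id
    barcode_seqs: dict[str, str] = field(default_factory=dict)  # barcode_id -> seq
    index_labels: dict[int, str] = field(default_factory=dict)  # zone -> index label

    def condition(self, well: str) -> Condition:
        return self.wells[well][0]

    def zone(self, well: str) -> int:
        return self.wells[well][1]

    def to_frame(self) -> pd.DataFrame:
        """Layout as a tidy table, one row per well in row-major order."""
        rows = []
        for w in ALL_WELLS:
            cond, zone = self.wells[w]
            bc = self.barcodes.get(w)
            rows.append(
                {
                    "plate_id": self.plate_id,
                    "well": w,
                    "zone": zone,
                    "rna_pg": cond.rna,
                    "tso_uM": cond.tso,
                    "rtp_uM": cond.rtp,
                    "enzyme": cond.enzyme,
                    "control_type": cond.control_type,
                    "barcode_id": bc,
                    "barcode_seq": self.barcode_seqs.get(bc) if bc else None,
                    "index_label": self.index_labels.get(zone),
                    "seed": self.seed,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlateLayout":
        first = df.iloc[0]
        layout = cls(
            plate_id=str(first["plate_id"]),
            enzyme=str(first["enzyme"]),
            replicate_index=0,
            seed=int(first["seed"]),
        )
        for _, r in df.iterrows():
            cond = Condition(
                tso=None if pd.isna(r["tso_uM"]) else float(r["tso_uM"]),
                rtp=None if pd.isna(r["rtp_uM"]) else float(r["rtp_uM"]),
                rna=None if pd.isna(r["rna_pg"]) else float(r["rna_pg"]),
                enzyme=str(r["enzyme"]),
            )
            zone = int(r["zone"])
            layout.wells[str(r["well"])] = (cond, zone)
            if not pd.isna(r["barcode_id"]):
                layout.barcodes[str(r["well"])] = str(r["barcode_id"])
                layout.barcode_seqs[str(r["barcode_id"])] = str(r["barcode_seq"])
            if not pd.isna(r["index_label"]):
                layout.index_labels[zone] = str(r["index_label"])
        return layout

    @classmethod
    def from_csv(cls, path) -> "PlateLayout":
        return cls.from_frame(pd.read_csv(path))


def enumerate_conditions(levels: FactorLevels) -> list[Condition]:
    """Cartesian product of the four factors, no controls.

    Deterministic nested-loop order with the enzyme outermost, then TSO,
    RTP and RNA in declared order; the default series yields 648
    combinations (9 × 6 × 6 × 2).
    """
    return [
        Condition(tso=t, rtp=p, rna=r, enzyme=e)
        for e in levels.enzymes
        for t in levels.tso_molarities
        for p in levels.rtp_molarities
        for r in levels.rna_masses
    ]


def build_zone_plans(
    conditions: list[Condition],
    levels: FactorLevels,
    control_rules: ControlRules = ControlRules(),
    zone_size: int = 64,
) -> list[ZonePlan]:
    """Partition one enzyme's conditions into per-RNA-mass zones of 64 wells.

    ``conditions`` must hold exactly one enzyme's experimental grid (the
    full TSO×RTP product for every RNA mass).  Each zone receives the
    54-member grid plus nine no-RTP controls (one per TSO level) and one
    no-RNA control.
    """
    enzymes = {c.enzyme for c in conditions}
    if len(enzymes) != 1:
        raise DesignError(f"zone plans are per-plate (one enzyme), got {sorted(enzymes)}")
    (enzyme,) = enzymes

    grid = len(levels.tso_molarities) * len(levels.rtp_molarities)
    n_no_rtp = len(levels.tso_molarities) if control_rules.no_rtp_per_tso_level else 0
    n_controls = n_no_rtp + control_rules.n_no_rna
    if grid + n_controls > zone_size:
        raise CapacityError(
            f"grid {len(levels.tso_molarities)}x{len(levels.rtp_molarities)} "
            f"plus {n_controls} controls exceeds the {zone_size}-well zone "
            f"({grid + n_controls} > {zone_size})"
        )
    if grid + n_controls < zone_size:
        raise CapacityError(
            f"grid {len(levels.tso_molarities)}x{len(levels.rtp_molarities)} "
            f"plus {n_controls} controls underfills the {zone_size}-well zone "
            f"({grid + n_controls} < {zone_size})"
        )

    # median levels for the no-RNA control (its molarities are arbitrary)
    med_tso = levels.tso_molarities[len(levels.tso_molarities) // 2]
    med_rtp = levels.rtp_molarities[len(levels.rtp_molarities) // 2]

    by_rna: dict[float, list[Condition]] = {r: [] for r in levels.rna_masses}
    for c in conditions:
        if c.is_control:
            raise DesignError("controls are added here; pass experimental conditions only")
        if c.rna not in by_rna:
            raise DesignError(f"condition RNA mass {c.rna} not in declared levels")
        by_rna[c.rna].append(c)

    plans = []
    for zone_id, rna in enumerate(levels.rna_masses, start=1):
        members = list(by_rna[rna])
        triples = {(c.tso, c.rtp) for c in members}
        expected = set(itertools.product(levels.tso_molarities, levels.rtp_molarities))
        if triples != expected or len(members) != grid:
            raise DesignError(f"zone {zone_id}: conditions do not cover the TSO×RTP grid exactly once")
        if control_rules.no_rtp_per_tso_level:
            members += [
                Condition(tso=t, rtp=None, rna=rna, enzyme=enzyme)
                for t in levels.tso_molarities
            ]
        members += [
            Condition(tso=med_tso, rtp=med_rtp, rna=None, enzyme=enzyme)
        ] * control_rules.n_no_rna
        plans.append(ZonePlan(zone_id=zone_id, rna_mass=rna, members=members))
    return plans


def default_interleaving(n_zones: int = 6) -> dict[int, list[str]]:
    """Zone -> well set: zone z owns every column c with ((c-1) mod n) + 1 == z,
    all 16 rows.  With 6 zones each owns 4 full columns (64 wells), so a
    zone's contents can be collected with an 8-channel pipette in two
    strokes per column.  Wells are listed in row-major canonical order."""
    if N_COLS % n_zones != 0:
        raise DesignError(f"{n_zones} zones do not tile {N_COLS} columns evenly")
    out: dict[int, list[str]] = {z: [] for z in range(1, n_zones + 1)}
    for r in range(16):
        for c in range(N_COLS):
            out[(c % n_zones) + 1].append(well_name(r, c))
    return out


def _stage_rng(seed: int, stage: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), stage, *extra)))


def randomize_layout(
    zone_plans: list[ZonePlan],
    plate_id: str,
    seed: int,
    enzyme: str | None = None,
    replicate_index: int = 0,
    interleaving: dict[int, list[str]] | None = None,
) -> PlateLayout:
    """Place each zone's members on its fixed well set by a seeded uniform
    permutation.  The zone→well-set mapping is the interleaving pattern and
    never changes; only member→well within a zone is randomized.  The same
    seed reproduces a bit-identical layout."""
    if interleaving is None:
        interleaving = default_interleaving(len(zone_plans))
    if enzyme is None:
        enzyme = zone_plans[0].members[0].enzyme
    layout = PlateLayout(
        plate_id=plate_id, enzyme=enzyme, replicate_index=replicate_index, seed=int(seed)
    )
    for plan in zone_plans:
        wells = interleaving[plan.zone_id]
        if len(wells) != len(plan.members):
            raise DesignError(
                f"zone {plan.zone_id}: {len(plan.members)} members for {len(wells)} wells"
            )
        rng = _stage_rng(seed, _STAGE_PERMUTE, plan.zone_id)
        order = rng.permutation(len(plan.members))
        for w, i in zip(wells, order):
            layout.wells[w] = (plan.members[i], plan.zone_id)
        if plan.index_label is not None:
            layout.index_labels[plan.zone_id] = plan.index_label
    return layout


def assign_barcodes(layout: PlateLayout, pool: BarcodePool, seed: int | None = None) -> PlateLayout:
    """Draw 64 barcodes from the pool without replacement and spread them over
    each zone's wells by a per-zone seeded permutation.

    The same 64-barcode set serves all six zones of the plate: the barcode
    identifies the well within a zone, the sequencing index identifies the
    zone.  Modifies ``layout`` in place and returns it.
    """
    zones = sorted({z for _, z in layout.wells.values()})
    per_zone = {z: [w for w in ALL_WELLS if layout.wells[w][1] == z] for z in zones}
    n_needed = max(len(ws) for ws in per_zone.values())
    if len(pool) < n_needed:
        raise DesignError(f"barcode pool of {len(pool)} cannot cover {n_needed}-well zones")
    if seed is None:
        seed = layout.seed
    rng = _stage_rng(seed, _STAGE_BARCODE)
    ids = sorted(pool.entries)
    drawn = [ids[i] for i in rng.choice(len(ids), size=n_needed, replace=False)]
    for z in zones:
        zrng = _stage_rng(seed, _STAGE_BARCODE, z)
        order = zrng.permutation(n_needed)
        for w, i in zip(per_zone[z], order):
            layout.barcodes[w] = drawn[i]
    layout.barcode_seqs = {b: pool.entries[b] for b in drawn}
    return layout


def layout_fingerprint(layout: PlateLayout) -> tuple[tuple[str, str], ...]:
    """Control wells in row-major order with their subtype — the layout's
    identifying fingerprint (equal layouts give equal signatures)."""
    return tuple(
        (w, layout.wells[w][0].control_type)
        for w in ALL_WELLS
        if layout.wells[w][0].is_control
    )


def build_replicate_layouts(
    levels: FactorLevels = FactorLevels(),
    pool: BarcodePool | None = None,
    n_replicates: int = 4,
    master_seed: int = 1,
    control_rules: ControlRules = ControlRules(),
) -> list[PlateLayout]:
    """Full screen: ``n_replicates`` randomized plates per enzyme, each with
    its own derived seed, plus zone index labels (replicate r, zone z gets
    index ``idx{(r-1)*n_zones+z:02d}``; the same index series is reused
    across enzymes, mirroring one sequencing pool per enzyme)."""
    if pool is None:
        pool = BarcodePool.random_pool(seed=master_seed)
    n_zones = len(levels.rna_masses)
    all_conditions = enumerate_conditions(levels)
    layouts = []
    for enzyme in levels.enzymes:
        econds = [c for c in all_conditions if c.enzyme == enzyme]
        for rep in range(1, n_replicates + 1):
            plans = build_zone_plans(econds, levels, control_rules)
            for plan in plans:
                plan.index_label = f"idx{(rep - 1) * n_zones + plan.zone_id:02d}"
            enzyme_ix = levels.enzymes.index(enzyme)
            plate_seed = int(
                np.random.SeedSequence((int(master_seed), 1000 + enzyme_ix, rep))
                .generate_state(1)[0]
                % (2**31)
            )
            layout = randomize_layout(
                plans, plate_id=f"{enzyme}_rep{rep}", seed=plate_seed,
                enzyme=enzyme, replicate_index=rep,
            )
            assign_barcodes(layout, pool)
            layouts.append(layout)
    return layouts


def pcr_cycles(
    rna_pg: float,
    rna_masses: tuple[float, ...] = FactorLevels().rna_masses,
    base_cycles: int = 18,
    step: int = 3,
) -> int:
    """PCR cycle count for a zone's pooled amplification.

    Amplification is scaled to the starting RNA so every pool reaches
    comparable sequence coverage: the largest mass gets ``base_cycles`` and
    each 10-fold dilution three more, giving 18, 21, 24, 27, 30 and 33
    cycles from 100 ng down to 1 pg with the default series.
    """
    ordered = sorted(rna_masses, reverse=True)
    if rna_pg not in ordered:
        raise DesignError(f"RNA mass {rna_pg} pg not a declared level")
    return base_cycles + step * ordered.index(rna_pg)
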