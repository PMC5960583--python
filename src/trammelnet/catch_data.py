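"""Data model, file I/O and deterministic catch-processing rules.

The statistical unit of the gear trial is the *netting wall*: a ~100 m
section of trammel net.  Walls are nested in nets, nets in fishing trips
run by one of a handful of boats.  Each caught organism (a
:class:`CatchItem`) is attached to the wall it was entangled in, except
for the small-invertebrate fraction that disentangles passively during
hauling and can only be recorded for the whole net
(:class:`NetPoolRecord`).

The deterministic processing rules live here: allometric length-to-weight
conversion, length-class binning (class maximum convention), conspecific
mean imputation of missing lengths, first-sale revenue from mean category
prices, and scaling of the 20-L pooled-fraction subsample to the net
total.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "WallType",
    "Fate",
    "NET_LEVEL",
    "NettingWallRecord",
    "CatchItem",
    "NetPoolRecord",
    "LengthWeightParams",
    "PriceTable",
    "CatchParseError",
    "read_catch_tables",
    "write_catch_tables",
    "read_price_table",
    "read_lw_params",
    "length_to_weight",
    "assign_length_class",
    "impute_length",
    "item_revenue",
    "pool_discards_to_net",
    "wall_totals",
]


class WallType(str, enum.Enum):
    """Netting-wall gear type: fiber material, optionally with a greca.

    PMF is the standard polyfilament net, MMF the polyethylene
    multi-monofilament alternative, and MMF_GRECA an MMF wall with a
    ~20 cm guarding strip sewn to its bottom edge.
    """

    PMF = "PMF"
    MMF = "MMF"
    MMF_GRECA = "MMF_GRECA"


class Fate(str, enum.Enum):
    MARKETABLE = "MARKETABLE"
    DISCARD = "DISCARD"


#: wall_id marker for catch fractions recorded at whole-net level only.
NET_LEVEL = "NET_LEVEL"


class CatchParseError(ValueError):
    """Raised when a delimited catch table violates the file contract."""


@dataclass(frozen=True)
class NettingWallRecord:
    """One netting wall: the sample unit of the trial."""

    wall_id: str
    trip_id: str
    boat_id: str
    net_id: str
    wall_index: int
    wall_type: WallType
    depth_m: float
    soak_h: float

    def __post_init__(self) -> None:
        if self.wall_index < 1:
            raise ValueError(f"wall_index must be >= 1, got {self.wall_index}")
        if self.depth_m <= 0:
            raise ValueError(f"depth_m must be > 0, got {self.depth_m}")
        if self.soak_h <= 0:
            raise ValueError(f"soak_h must be > 0, got {self.soak_h}")


@dataclass(frozen=True)
class CatchItem:
    """One caught organism, or one pooled-fraction entry at net level."""

    item_id: str
    wall_id: str  # a wall_id, or the NET_LEVEL marker
    species: str
    fate: Fate
    length_cm: float | None = None
    length_class_upper_cm: float | None = None
    weight_kg: float | None = None
    alive_on_arrival: bool | None = None
    commercial_category: str | None = None

    def __post_init__(self) -> None:
        if self.fate is Fate.MARKETABLE and not self.commercial_category:
            raise ValueError(
                f"item {self.item_id}: marketable items need a commercial_category"
            )
        for name in ("length_cm", "length_class_upper_cm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"item {self.item_id}: {name} must be > 0")
        if self.weight_kg is not None and self.weight_kg < 0:
            raise ValueError(f"item {self.item_id}: weight_kg must be >= 0")

    @property
    def any_length(self) -> float | None:
        """Measured length if present, else the class upper bound."""
        return self.length_cm if self.length_cm is not None else self.length_class_upper_cm


@dataclass(frozen=True)
class NetPoolRecord:
    """Pooled invertebrate fraction of one net: volume plus a 20-L subsample."""

    net_id: str
    total_volume_l: float
    subsample_volume_l: float
    subsample_weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_volume_l < 0:
            raise ValueError(f"net {self.net_id}: total_volume_l must be >= 0")
        if self.subsample_weights and self.subsample_volume_l <= 0:
            raise ValueError(
                f"net {self.net_id}: subsample_volume_l must be > 0 with nonempty weights"
            )
        if any(w < 0 for w in self.subsample_weights.values()):
            raise ValueError(f"net {self.net_id}: negative subsample weight")


@dataclass(frozen=True)
class LengthWeightParams:
    """Allometric coefficients W = a L^b, in the g-cm convention."""

    species: str
    a: float
    b: float
    length_type: str = "TOTAL_LENGTH"  # or CARAPACE_LENGTH
    units: str = "g_cm"

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("length-weight coefficient a must be > 0")
        if not (1.0 <= self.b <= 4.0):
            raise ValueError(f"allometric exponent b={self.b} outside [1, 4]")


class PriceTable:
    """First-sale prices per commercial category and trip.

    ``mean_price`` averages over all trips for a category, which is the
    convention used to value marketable items.
    """

    def __init__(self, entries: Iterable[tuple[str, str, float]]):
        self.entries = list(entries)
        by_cat: dict[str, list[float]] = {}
        for cat, _trip, price in self.entries:
            if price < 0:
                raise ValueError(f"negative price for category {cat!r}")
            by_cat.setdefault(cat, []).append(price)
        self._mean = {c: sum(v) / len(v) for c, v in by_cat.items()}

    def mean_price(self, category: str) -> float:
        try:
            return self._mean[category]
        except KeyError:
            raise KeyError(f"no price entries for commercial category {category!r}") from None

    def categories(self) -> list[str]:
        return sorted(self._mean)


# ---------------------------------------------------------------------------
# File I/O.  Plain csv (UTF-8, header mandatory); empty string means absent.
# ---------------------------------------------------------------------------

WALL_COLUMNS = ["wall_id", "trip_id", "boat_id", "net_id", "wall_index",
                "wall_type", "depth_m", "soak_h"]
ITEM_COLUMNS = ["item_id", "wall_id", "species", "fate", "length_cm",
                "length_class_upper_cm", "weight_kg", "alive_on_arrival",
                "commercial_category"]
POOL_COLUMNS = ["net_id", "total_volume_l", "subsample_volume_l", "species",
                "subsample_weight_kg"]


def _read_rows(path: Path, required: Sequence[str]) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CatchParseError(f"{path}: empty file, header row required")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise CatchParseError(f"{path}: missing column(s) {', '.join(missing)}")
        return list(reader)


def _opt_float(value: str) -> float | None:
    return None if value == "" else float(value)


def _opt_bool(value: str) -> bool | None:
    if value == "":
        return None
    if value in ("True", "true", "1"):
        return True
    if value in ("False", "false", "0"):
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def read_catch_tables(
    walls_path: str | Path,
    items_path: str | Path,
    pools_path: str | Path | None = None,
) -> tuple[list[NettingWallRecord], list[CatchItem], list[NetPoolRecord]]:
    """Read the wall, item and (optional) net-pool tables.

    All foreign keys are checked: item rows must reference an existing
    wall (or carry the NET_LEVEL marker) and pool rows an existing net.
    Row order is preserved.
    """
    walls_path, items_path = Path(walls_path), Path(items_path)
    walls: list[NettingWallRecord] = []
    for lineno, row in enumerate(_read_rows(walls_path, WALL_COLUMNS), start=2):
        try:
            walls.append(NettingWallRecord(
                wall_id=row["wall_id"], trip_id=row["trip_id"],
                boat_id=row["boat_id"], net_id=row["net_id"],
                wall_index=int(row["wall_index"]),
                wall_type=WallType(row["wall_type"]),
                depth_m=float(row["depth_m"]), soak_h=float(row["soak_h"]),
            ))
        except (ValueError, KeyError) as exc:
            raise CatchParseError(f"{walls_path}, line {lineno}: {exc}") from exc

    wall_ids = {w.wall_id for w in walls}
    if len(wall_ids) != len(walls):
        raise CatchParseError(f"{walls_path}: duplicated wall_id")
    seen_index: set[tuple[str, int]] = set()
    net_owner: dict[str, tuple[str, str]] = {}
    for w in walls:
        key = (w.net_id, w.wall_index)
        if key in seen_index:
            raise CatchParseError(
                f"{walls_path}: duplicate wall_index {w.wall_index} in net {w.net_id}")
        seen_index.add(key)
        owner = (w.trip_id, w.boat_id)
        if net_owner.setdefault(w.net_id, owner) != owner:
            raise CatchParseError(
                f"{walls_path}: net {w.net_id} spans several trips/boats")

    items: list[CatchItem] = []
    for lineno, row in enumerate(_read_rows(items_path, ITEM_COLUMNS), start=2):
        try:
            item = CatchItem(
                item_id=row["item_id"], wall_id=row["wall_id"],
                species=row["species"], fate=Fate(row["fate"]),
                length_cm=_opt_float(row["length_cm"]),
                length_class_upper_cm=_opt_float(row["length_class_upper_cm"]),
                weight_kg=_opt_float(row["weight_kg"]),
                alive_on_arrival=_opt_bool(row["alive_on_arrival"]),
                commercial_category=row["commercial_category"] or None,
            )
        except ValueError as exc:
            raise CatchParseError(f"{items_path}, line {lineno}: {exc}") from exc
        if item.wall_id != NET_LEVEL and item.wall_id not in wall_ids:
            raise CatchParseError(
                f"{items_path}, line {lineno}: item {item.item_id} references "
                f"unknown wall_id {item.wall_id!r}")
        items.append(item)

    pools: list[NetPoolRecord] = []
    if pools_path is not None:
        net_ids = {w.net_id for w in walls}
        grouped: dict[str, dict] = {}
        order: list[str] = []
        for lineno, row in enumerate(_read_rows(Path(pools_path), POOL_COLUMNS), start=2):
            nid = row["net_id"]
            if nid not in net_ids:
                raise CatchParseError(
                    f"{pools_path}, line {lineno}: unknown net_id {nid!r}")
            try:
                tv, sv = float(row["total_volume_l"]), float(row["subsample_volume_l"])
                wkg = float(row["subsample_weight_kg"])
            except ValueError as exc:
                raise CatchParseError(f"{pools_path}, line {lineno}: {exc}") from exc
            g = grouped.setdefault(nid, {"tv": tv, "sv": sv, "weights": {}})
            if nid not in order:
                order.append(nid)
            if (g["tv"], g["sv"]) != (tv, sv):
                raise CatchParseError(
                    f"{pools_path}, line {lineno}: inconsistent volumes for net {nid}")
            g["weights"][row["species"]] = wkg
        for nid in order:
            g = grouped[nid]
            try:
                pools.append(NetPoolRecord(nid, g["tv"], g["sv"], g["weights"]))
            except ValueError as exc:
                raise CatchParseError(f"{pools_path}: net {nid}: {exc}") from exc
    return walls, items, pools


def write_catch_tables(
    walls: Sequence[NettingWallRecord],
    items: Sequence[CatchItem],
    pools: Sequence[NetPoolRecord],
    walls_path: str | Path,
    items_path: str | Path,
    pools_path: str | Path,
) -> None:
    """Write the three tables in the format ``read_catch_tables`` accepts."""

    def fmt(v) -> str:
        if v is None:
            return ""
        if isinstance(v, bool):
            return str(v)
        if isinstance(v, float):
            return repr(float(v))  # builtin-float repr round-trips exactly
        return str(v)

    with open(walls_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(WALL_COLUMNS)
        for r in walls:
            w.writerow([r.wall_id, r.trip_id, r.boat_id, r.net_id, r.wall_index,
                        r.wall_type.value, fmt(r.depth_m), fmt(r.soak_h)])
    with open(items_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(ITEM_COLUMNS)
        for it in items:
            w.writerow([it.item_id, it.wall_id, it.species, it.fate.value,
                        fmt(it.length_cm), fmt(it.length_class_upper_cm),
                        fmt(it.weight_kg), fmt(it.alive_on_arrival),
                        fmt(it.commercial_category)])
    with open(pools_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(POOL_COLUMNS)
        for p in pools:
            for sp in sorted(p.subsample_weights):
                w.writerow([p.net_id, fmt(p.total_volume_l),
                            fmt(p.subsample_volume_l), sp,
                            fmt(p.subsample_weights[sp])])


def read_price_table(path: str | Path) -> PriceTable:
    rows = _read_rows(Path(path), ["commercial_category", "trip_id", "price_eur_per_kg"])
    return PriceTable(
        (r["commercial_category"], r["trip_id"], float(r["price_eur_per_kg"]))
        for r in rows
    )


def read_lw_params(path: str | Path) -> dict[str, LengthWeightParams]:
    rows = _read_rows(Path(path), ["species", "a", "b", "length_type", "units"])
    return {
        r["species"]: LengthWeightParams(
            species=r["species"], a=float(r["a"]), b=float(r["b"]),
            length_type=r["length_type"], units=r["units"])
        for r in rows
    }


# ---------------------------------------------------------------------------
# Deterministic processing rules
# ---------------------------------------------------------------------------

def length_to_weight(params: LengthWeightParams, length_cm: float) -> float:
    """Convert a length (cm) to weight (kg) via W = a L^b.

    Coefficients are in the g-cm convention, hence the division by 1000.
    """
    if length_cm <= 0:
        raise ValueError(f"length_cm must be > 0, got {length_cm}")
    return params.a * length_cm ** params.b / 1000.0


def assign_length_class(length_cm: float, class_width_cm: float) -> float:
    """Upper bound of the half-open length class (k*w, (k+1)*w] containing L.

    10-cm classes are used for fish total length, 5-cm classes for
    lobster carapace length.  A length exactly on a class boundary
    belongs to the class it closes (23 -> 30 at width 10, but 20 -> 20).
    """
    if length_cm <= 0 or class_width_cm <= 0:
        raise ValueError("length and class width must be > 0")
    k = math.ceil(length_cm / class_width_cm)
    # guard against float fuzz just below a boundary multiple
    if (k - 1) * class_width_cm >= length_cm:
        k -= 1
    return k * class_width_cm


def impute_length(items: Sequence[CatchItem], species: str) -> float:
    """Mean length of sampled conspecifics, for items without a size record.

    Measured lengths and length-class upper bounds are pooled into one
    arithmetic mean.
    """
    lengths = [it.any_length for it in items
               if it.species == species and it.any_length is not None]
    if not lengths:
        raise ValueError(
            f"no conspecific length available for {species!r}; drop or flag the item")
    return sum(lengths) / len(lengths)


def item_revenue(weight_kg: float, category: str, prices: PriceTable) -> float:
    """First-sale revenue: weight times the trip-averaged category price."""
    if weight_kg < 0:
        raise ValueError("weight_kg must be >= 0")
    return weight_kg * prices.mean_price(category)


def pool_discards_to_net(
    items: Sequence[CatchItem], pool: NetPoolRecord | None
) -> dict[str, float]:
    """Per-species discard weight of one net: wall items plus scaled pool.

    The 20-L subsample composition is scaled linearly by
    total_volume / subsample_volume; if the total volume does not exceed
    the subsample volume the subsample weights enter unscaled (the whole
    pool was weighed).
    """
    totals: dict[str, float] = {}
    for it in items:
        if it.fate is Fate.DISCARD and it.wall_id != NET_LEVEL and it.weight_kg:
            totals[it.species] = totals.get(it.species, 0.0) + it.weight_kg
    if pool is not None and pool.subsample_weights:
        if pool.total_volume_l > pool.subsample_volume_l:
            scale = pool.total_volume_l / pool.subsample_volume_l
        else:
            scale = 1.0
        for sp, wkg in pool.subsample_weights.items():
            totals[sp] = totals.get(sp, 0.0) + wkg * scale
    return totals


def wall_totals(
    walls: Sequence[NettingWallRecord],
    items: Sequence[CatchItem],
    fate: Fate,
    prices: PriceTable | None = None,
) -> dict[str, float]:
    """Per-wall cumulative amount: discard biomass (kg) or revenue (Euros).

    Net-level pooled items are excluded (they cannot be attributed to a
    wall).  For revenue, every marketable item must carry a weight.
    """
    totals = {w.wall_id: 0.0 for w in walls}
    for it in items:
        if it.fate is not fate or it.wall_id == NET_LEVEL:
            continue
        if it.weight_kg is None:
            raise ValueError(f"item {it.item_id} has no weight; process lengths first")
        if fate is Fate.MARKETABLE:
            if prices is None:
                raise ValueError("price table required for revenue totals")
            totals[it.wall_id] += item_revenue(it.weight_kg, it.commercial_category, prices)
        else:
            totals[it.wall_id] += it.weight_kg
    return totals
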