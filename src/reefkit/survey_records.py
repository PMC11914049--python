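"""Parsing and numeric resolution of semi-quantitative benthic cover tables.

Long-running harbor survey programs record hard-coral cover per taxon with a
mix of numbers, ranges ("20-30"), and the semi-quantitative symbols "R"
(rare, < 1% cover) and "+" (1-5% cover); a blank cell means *no survey*, which
is distinct from a recorded 0% cover.  This module turns such tables into
fully numeric records using the conventions of the source program:

* a range resolves to its midpoint (the median of an interval);
* in the *total-cover* column, "R" resolves to 0.5% and "+" to 3.0%;
* in *per-taxon* columns, "R" and "+" are resolved jointly by the R-unit
  allocation rule: count "R" as 1 unit and "+" as 6 units, spread the
  difference between the recorded total and the sum of numerically recorded
  taxa evenly over the units, and set all symbolic entries to 0 when that
  difference is not positive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed taxon vocabulary, in canonical column order.
TAXA: tuple[str, ...] = (
    "acropora",
    "pocillopora",
    "montipora",
    "porites",
    "faviidae",
    "millepora",
    "other_hard",
)

SUBSTRATES = frozenset({"artificial", "natural"})
METHODS = frozenset({"quadrat", "belt_transect", "spot_check", "manta", "snorkel"})
SEDIMENTATION_RANKS = frozenset({"I", "II", "III", "IV"})

#: R-unit weights for the allocation rule: "+" counts as six Rs.
R_UNITS = {"rare_symbol": 1, "plus_symbol": 6}

#: Fixed resolutions for symbols in the *total* column.
TOTAL_SYMBOL_PERCENT = {"rare_symbol": 0.5, "plus_symbol": 3.0}

_RANGE_RE = re.compile(
    r"^\s*(\d+(?:\.\d+)?)\s*(?:[-–—~]|to)\s*(\d+(?:\.\d+)?)\s*$"
)
_NUMBER_RE = re.compile(r"^\s*\d+(?:\.\d+)?\s*$")


class SurveyParseError(ValueError):
    """A cell or row could not be parsed under the documented schema."""


class SurveyValidationError(ValueError):
    """A parsed record violates a vocabulary or consistency invariant."""


@dataclass(frozen=True)
class CoverEntry:
    """One cover cell: the raw token, its kind, and the resolved percent.

    ``resolved_percent`` is ``None`` for ``missing`` cells and for the
    symbolic kinds (``rare_symbol``/``plus_symbol``), whose numeric value
    depends on context (total column vs taxon allocation).
    """

    raw_token: str
    kind: str  # numeric | range | rare_symbol | plus_symbol | zero | missing
    resolved_percent: float | None = None

    @property
    def is_symbolic(self) -> bool:
        return self.kind in R_UNITS

    @property
    def is_missing(self) -> bool:
        return self.kind == "missing"


MISSING_ENTRY = CoverEntry(raw_token="", kind="missing")


@dataclass
class SurveyRecord:
    """One validated survey observation (one row of the input table)."""

    record_id: str
    site_id: str
    substrate: str
    year: int
    elevation_lwl_m: float
    method: str
    taxon_entries: dict[str, CoverEntry]
    total_entry: CoverEntry
    slope_deg: float | None = None
    colony_counts: dict[str, float] = field(default_factory=dict)
    max_diameter_cm: dict[str, float] = field(default_factory=dict)
    sedimentation_rank: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.taxon_entries) - set(TAXA)
        if unknown:
            raise SurveyValidationError(
                f"record {self.record_id!r}: unknown taxa {sorted(unknown)}"
            )
        if self.substrate not in SUBSTRATES:
            raise SurveyValidationError(
                f"record {self.record_id!r}: substrate {self.substrate!r} not in "
                f"{sorted(SUBSTRATES)}"
            )
        if self.method not in METHODS:
            raise SurveyValidationError(
                f"record {self.record_id!r}: method {self.method!r} not in "
                f"{sorted(METHODS)}"
            )
        if self.slope_deg is not None and not (0.0 <= self.slope_deg <= 90.0):
            raise SurveyValidationError(
                f"record {self.record_id!r}: slope {self.slope_deg} outside [0, 90]"
            )
        if self.sedimentation_rank is not None and (
            self.sedimentation_rank not in SEDIMENTATION_RANKS
        ):
            raise SurveyValidationError(
                f"record {self.record_id!r}: sedimentation rank "
                f"{self.sedimentation_rank!r} not in I..IV"
            )

    @property
    def depth_below_lwl_m(self) -> float:
        """Depth below low water level (positive downward)."""
        return -self.elevation_lwl_m


def parse_entry(token: str) -> CoverEntry:
    """Parse one raw cover cell into a :class:`CoverEntry`.

    Empty cells are *missing* (no survey), "0" is a recorded zero, ranges
    resolve to their midpoint, and "R"/"+" stay symbolic for later
    context-dependent resolution.

    Raises
    ------
    SurveyParseError
        For malformed numerics, inverted ranges, or unrecognized tokens.
    """
    raw = token.strip() if isinstance(token, str) else ""
    if raw == "" or raw.lower() in {"na", "nan"}:
        return MISSING_ENTRY
    if raw in {"R", "r"}:
        return CoverEntry(raw_token=raw, kind="rare_symbol")
    if raw == "+":
        return CoverEntry(raw_token=raw, kind="plus_symbol")
    m = _RANGE_RE.match(raw)
    if m:
        lo, hi = float(m.group(1)), float(m.group(2))
        if lo > hi:
            raise SurveyParseError(f"inverted range in cell {raw!r} ({lo} > {hi})")
        mid = (lo + hi) / 2.0
        _check_percent(mid, raw)
        return CoverEntry(raw_token=raw, kind="range", resolved_percent=mid)
    if _NUMBER_RE.match(raw):
        value = float(raw)
        _check_percent(value, raw)
        if value == 0.0:
            return CoverEntry(raw_token=raw, kind="zero", resolved_percent=0.0)
        return CoverEntry(raw_token=raw, kind="numeric", resolved_percent=value)
    raise SurveyParseError(f"unrecognized cover token {raw!r}")


def _check_percent(value: float, raw: str) -> None:
    if not (0.0 <= value <= 100.0):
        raise SurveyParseError(f"cover {raw!r} resolves to {value}, outside [0, 100]")


def resolve_total(entry: CoverEntry) -> float:
    """Resolve a *total-cover* entry to percent.

    "R" is 0.5% and "+" is 3.0% in the total column; numeric, zero and range
    entries keep their resolved value.

    Raises
    ------
    SurveyValidationError
        If the entry is missing (no survey conducted: the record carries no
        usable total).
    """
    if entry.is_missing:
        raise SurveyValidationError("total entry is missing (no data)")
    if entry.kind in TOTAL_SYMBOL_PERCENT:
        return TOTAL_SYMBOL_PERCENT[entry.kind]
    assert entry.resolved_percent is not None
    return entry.resolved_percent


def allocate_taxon_cover(
    record: SurveyRecord, *, tolerance: float = 1e-9
) -> dict[str, float]:
    """Resolve all per-taxon entries of ``record`` to percents.

    Symbolic entries are allocated from the gap between the resolved total and
    the sum of numerically recorded taxa: with ``nR`` total R-units ("+" = 6
    units) and ``diff = total - sum(numeric)``, each unit is worth
    ``diff / nR`` when ``diff > 0`` and 0 otherwise.  Numeric entries are
    never rescaled; missing entries are omitted from the result.

    Raises
    ------
    SurveyValidationError
        If the total is missing, or the resolved percents sum above
        ``100 + tolerance``.
    """
    total = resolve_total(record.total_entry)
    numeric: dict[str, float] = {}
    units: dict[str, int] = {}
    for taxon, entry in record.taxon_entries.items():
        if entry.is_missing:
            continue
        if entry.is_symbolic:
            units[taxon] = R_UNITS[entry.kind]
        else:
            assert entry.resolved_percent is not None
            numeric[taxon] = entry.resolved_percent

    out = dict(numeric)
    if units:
        n_r = sum(units.values())
        diff = total - sum(numeric.values())
        unit_value = diff / n_r if diff > 0 else 0.0
        for taxon, n_units in units.items():
            out[taxon] = n_units * unit_value

    allocated_sum = sum(out.values())
    if allocated_sum > 100.0 + tolerance:
        raise SurveyValidationError(
            f"record {record.record_id!r}: resolved taxon covers sum to "
            f"{allocated_sum:.6g}% > 100%"
        )
    return out


# ---------------------------------------------------------------------------
# CSV I/O

_BASE_COLUMNS = (
    "record_id",
    "site_id",
    "substrate",
    "year",
    "elevation_lwl_m",
    "slope_deg",
    "method",
    "total",
)
_OPTIONAL_SCALARS = ("slope_deg", "sedimentation_rank")


def read_survey_table(
    path: str | Path, *, allowed_sites: Iterable[str] | None = None
) -> list[SurveyRecord]:
    """Read and validate a survey CSV into :class:`SurveyRecord` objects.

    The schema is one row per record with columns ``record_id, site_id,
    substrate, year, elevation_lwl_m, slope_deg, method, total`` followed by
    the seven taxon columns, then optional ``colony_<taxon>``,
    ``maxdiam_<taxon>`` and ``sedimentation_rank`` columns.  Unknown columns,
    vocabulary violations and duplicate record ids are load errors that name
    the offending row.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    known = set(_BASE_COLUMNS) | set(TAXA) | {"sedimentation_rank"}
    known |= {f"colony_{t}" for t in TAXA} | {f"maxdiam_{t}" for t in TAXA}
    unknown_cols = [c for c in frame.columns if c not in known]
    if unknown_cols:
        raise SurveyParseError(f"{path.name}: unknown columns {unknown_cols}")
    required = [c for c in _BASE_COLUMNS if c not in _OPTIONAL_SCALARS] + list(TAXA)
    missing_cols = [c for c in required if c not in frame.columns]
    if missing_cols:
        raise SurveyParseError(f"{path.name}: missing columns {missing_cols}")

    allowed = set(allowed_sites) if allowed_sites is not None else None
    records: list[SurveyRecord] = []
    seen_ids: set[str] = set()
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        row_map = dict(zip(frame.columns, row))
        try:
            record = _record_from_row(row_map)
        except (SurveyParseError, SurveyValidationError) as exc:
            raise type(exc)(f"{path.name} row {row_number}: {exc}") from exc
        if record.record_id in seen_ids:
            raise SurveyParseError(
                f"{path.name} row {row_number}: duplicate record_id "
                f"{record.record_id!r}"
            )
        if allowed is not None and record.site_id not in allowed:
            raise SurveyValidationError(
                f"{path.name} row {row_number}: site {record.site_id!r} "
                f"not in the allowed site set"
            )
        seen_ids.add(record.record_id)
        records.append(record)

    by = pd.DataFrame(
        [(r.substrate, r.method, r.year) for r in records],
        columns=["substrate", "method", "year"],
    )
    logger.info(
        "loaded %d records from %s (%s)",
        len(records),
        path.name,
        "; ".join(
            f"{k}: {dict(by[k].value_counts())}" for k in ("substrate", "method")
        ),
    )
    return records


def _record_from_row(row: Mapping[str, str]) -> SurveyRecord:
    def _float(col: str, *, optional: bool = False) -> float | None:
        raw = str(row.get(col, "")).strip()
        if raw == "":
            if optional:
                return None
            raise SurveyParseError(f"missing value in column {col!r}")
        try:
            return float(raw)
        except ValueError as exc:
            raise SurveyParseError(f"bad number {raw!r} in column {col!r}") from exc

    taxon_entries = {t: parse_entry(str(row.get(t, ""))) for t in TAXA}
    colony = {
        t: v
        for t in TAXA
        if (v := _float(f"colony_{t}", optional=True)) is not None
    }
    for taxon, count in colony.items():
        if count < 0:
            raise SurveyValidationError(f"negative colony count for {taxon}")
    maxdiam = {
        t: v
        for t in TAXA
        if (v := _float(f"maxdiam_{t}", optional=True)) is not None
    }
    rank = str(row.get("sedimentation_rank", "")).strip() or None
    year_raw = str(row["year"]).strip()
    try:
        year = int(year_raw)
    except ValueError as exc:
        raise SurveyParseError(f"bad year {year_raw!r}") from exc
    return SurveyRecord(
        record_id=str(row["record_id"]).strip(),
        site_id=str(row["site_id"]).strip(),
        substrate=str(row["substrate"]).strip(),
        year=year,
        elevation_lwl_m=_float("elevation_lwl_m"),
        slope_deg=_float("slope_deg", optional=True),
        method=str(row["method"]).strip(),
        taxon_entries=taxon_entries,
        total_entry=parse_entry(str(row.get("total", ""))),
        colony_counts=colony,
        max_diameter_cm=maxdiam,
        sedimentation_rank=rank,
    )


def resolve_records(records: Iterable[SurveyRecord]) -> pd.DataFrame:
    """Resolve a batch of records into a numeric-only table.

    Records whose total entry is missing are excluded (no data).  The result
    has one row per usable record with resolved total and per-taxon percents,
    plus the design covariates needed downstream.
    """
    rows = []
    for record in records:
        if record.total_entry.is_missing:
            continue
        allocated = allocate_taxon_cover(record)
        row: dict[str, object] = {
            "record_id": record.record_id,
            "site_id": record.site_id,
            "substrate": record.substrate,
            "year": record.year,
            "elevation_lwl_m": record.elevation_lwl_m,
            "depth_below_lwl_m": record.depth_below_lwl_m,
            "slope_deg": record.slope_deg,
            "method": record.method,
            "total": resolve_total(record.total_entry),
        }
        for taxon in TAXA:
            row[taxon] = allocated.get(taxon)
        rows.append(row)
    return pd.DataFrame(rows)


def write_resolved_table(records: Iterable[SurveyRecord], path: str | Path) -> None:
    """Write the resolved (numeric-only) table mirroring the input schema."""
    resolve_records(records).to_csv(path, index=False, float_format="%.10g")
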