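"""Specimen measurement schema, CSV I/O and derived axial quantities.

The unit of observation is one fossil specimen with axial part lengths in
millimetres: cephalic parts (FAL, PGL, ORL), thoracic segment lengths
(LTS1..LTS13) and pygidial length (PYL).  Derived quantities (CEL, TRL,
BOL, relative segment lengths and boundary positions) are computed here,
as are per-stage summaries used by the allometric and gradient analyses.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional, Sequence

MERASPID = "meraspid"
HOLASPID = "holaspid"

#: Adult thoracic segment count; the holaspid period starts when it is reached.
HOLASPID_SEGMENTS = 13

MIN_DEGREE = 0
MAX_DEGREE = 12

LTS_COLUMNS = tuple(f"LTS{i}" for i in range(1, HOLASPID_SEGMENTS + 1))
CSV_COLUMNS = ("specimen_id", "period", "degree", "FAL", "PGL", "ORL",
               *LTS_COLUMNS, "PYL")

#: Numeric tolerance for additive identities (CEL + TRL = BOL etc.).
IDENTITY_TOL = 1e-12


class DataError(ValueError):
    """Raised for schema or invariant violations in specimen data."""


@dataclass(frozen=True)
class SpecimenMeasurement:
    """Axial lengths of one specimen; any part may be absent (``None``).

    ``lts`` holds one slot per thoracic segment the specimen possesses
    (``degree`` slots for meraspides, 13 for holaspides); a ``None`` slot
    means the segment exists but was not measured.
    """

    specimen_id: str
    period: str
    degree: Optional[int]
    fal: Optional[float] = None
    pgl: Optional[float] = None
    orl: Optional[float] = None
    lts: tuple = ()
    pyl: Optional[float] = None

    def n_segments(self) -> int:
        """Number of thoracic segments this specimen possesses."""
        if self.period == MERASPID:
            return self.degree if self.degree is not None else 0
        return HOLASPID_SEGMENTS

    def problems(self) -> list:
        """Return invariant violations as human-readable strings."""
        out = []
        if self.period not in (MERASPID, HOLASPID):
            out.append(f"unknown period {self.period!r}")
            return out
        if self.period == MERASPID:
            if self.degree is None:
                out.append("meraspid specimen without a degree")
            elif not MIN_DEGREE <= self.degree <= MAX_DEGREE:
                out.append(f"degree {self.degree} outside {MIN_DEGREE}..{MAX_DEGREE}")
            elif len(self.lts) != self.degree:
                out.append(
                    f"LTS count {len(self.lts)} != degree {self.degree}")
        else:
            if self.degree is not None:
                out.append("holaspid specimen with a meraspid degree")
            if len(self.lts) not in (0, HOLASPID_SEGMENTS):
                out.append(
                    f"holaspid LTS count {len(self.lts)} is neither 0 nor "
                    f"{HOLASPID_SEGMENTS}")
        for name, value in self._named_parts():
            if value is not None and not (value > 0 and math.isfinite(value)):
                out.append(f"non-positive length {name}={value!r}")
        return out

    def _named_parts(self):
        yield "FAL", self.fal
        yield "PGL", self.pgl
        yield "ORL", self.orl
        for i, v in enumerate(self.lts, start=1):
            yield f"LTS{i}", v
        yield "PYL", self.pyl


@dataclass(frozen=True)
class DerivedParts:
    """Sums and trunk-relative ratios derived from one specimen.

    Any field whose ingredients are absent is itself ``None``.
    ``rls[i-1]`` is segment *i* length / TRL; ``rps[i-1]`` is the relative
    position of its posterior boundary (cumulative RLS); ``rpyl`` is
    PYL / TRL, so ``sum(rls) + rpyl == 1``.
    """

    cel: Optional[float]
    trl: Optional[float]
    bol: Optional[float]
    rls: Optional[tuple]
    rps: Optional[tuple]
    rpyl: Optional[float]


def derive_parts(spec: SpecimenMeasurement) -> DerivedParts:
    """Compute CEL, TRL, BOL and the trunk-relative vectors for one specimen."""
    cel = None
    if spec.fal is not None and spec.pgl is not None and spec.orl is not None:
        cel = spec.fal + spec.pgl + spec.orl

    trl = rls = rps = rpyl = None
    trunk_complete = (spec.pyl is not None
                      and len(spec.lts) == spec.n_segments()
                      and all(v is not None for v in spec.lts))
    if trunk_complete:
        trl = sum(spec.lts) + spec.pyl
        if trl <= 0:
            raise DataError(
                f"specimen {spec.specimen_id}: non-positive trunk length {trl}")
        rls = tuple(v / trl for v in spec.lts)
        acc, pos = 0.0, []
        for r in rls:
            acc += r
            pos.append(acc)
        rps = tuple(pos)
        rpyl = spec.pyl / trl
        if any(b <= a for a, b in zip(rps, rps[1:])):
            raise DataError(
                f"specimen {spec.specimen_id}: RPS not strictly increasing")

    bol = cel + trl if (cel is not None and trl is not None) else None
    return DerivedParts(cel=cel, trl=trl, bol=bol, rls=rls, rps=rps, rpyl=rpyl)


_DERIVED_NAMES = ("CEL", "TRL", "BOL")


def derived_value(spec: SpecimenMeasurement, name: str) -> Optional[float]:
    """Look up a raw or derived length by column-style name (e.g. ``"LTS3"``)."""
    if name == "FAL":
        return spec.fal
    if name == "PGL":
        return spec.pgl
    if name == "ORL":
        return spec.orl
    if name == "PYL":
        return spec.pyl
    if name.startswith("LTS"):
        i = int(name[3:])
        if 1 <= i <= len(spec.lts):
            return spec.lts[i - 1]
        return None
    if name in _DERIVED_NAMES:
        d = derive_parts(spec)
        return getattr(d, name.lower())
    raise KeyError(f"unknown part name {name!r}")


# ---------------------------------------------------------------------------
# CSV I/O


@dataclass
class LoadResult:
    """Specimens parsed from a CSV plus per-row rejection warnings."""

    specimens: list
    warnings: list

    def __len__(self) -> int:
        return len(self.specimens)

    def __iter__(self) -> Iterator[SpecimenMeasurement]:
        return iter(self.specimens)


def _parse_cell(text: str, column: str, row_no: int):
    text = text.strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise DataError(f"row {row_no}: column {column} is not numeric: {text!r}")


def load_specimens(path) -> LoadResult:
    """Read the specimen CSV dialect.

    Unknown or missing header columns are a hard error.  Rows violating an
    invariant (bad period, LTS/degree mismatch, non-positive length) are
    rejected with a warning naming the row and specimen, not raised.
    """
    specimens, warns = [], []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise DataError(f"{path}: empty file")
        header = [h.strip() for h in header]
        unknown = [h for h in header if h not in CSV_COLUMNS]
        if unknown:
            raise DataError(f"{path}: unknown column(s) {unknown}")
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise DataError(f"{path}: missing column(s) {missing}")
        idx = {c: header.index(c) for c in CSV_COLUMNS}

        for row_no, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            try:
                spec = _parse_row(row, idx, row_no)
            except DataError as exc:
                warns.append(str(exc))
                continue
            probs = spec.problems()
            if probs:
                warns.append(
                    f"row {row_no} (specimen {spec.specimen_id}): rejected: "
                    + "; ".join(probs))
                continue
            specimens.append(spec)
    for w in warns:
        warnings.warn(w, stacklevel=2)
    return LoadResult(specimens=specimens, warnings=warns)


def _parse_row(row, idx, row_no) -> SpecimenMeasurement:
    def cell(col):
        j = idx[col]
        return row[j] if j < len(row) else ""

    sid = cell("specimen_id").strip()
    period = cell("period").strip().lower()
    deg_text = cell("degree").strip()
    degree = None
    if deg_text:
        try:
            degree = int(deg_text)
        except ValueError:
            raise DataError(f"row {row_no}: degree is not an integer: {deg_text!r}")

    raw_lts = [_parse_cell(cell(c), c, row_no) for c in LTS_COLUMNS]
    if period == MERASPID and degree is not None and 0 <= degree <= MAX_DEGREE:
        extra = [LTS_COLUMNS[i] for i in range(degree, HOLASPID_SEGMENTS)
                 if raw_lts[i] is not None]
        if extra:
            raise DataError(
                f"row {row_no} (specimen {sid}): LTS count != degree: values in "
                f"{extra} beyond degree {degree}")
        lts = tuple(raw_lts[:degree])
    else:
        # trim trailing unmeasured slots for holaspides with no thorax data
        if all(v is None for v in raw_lts):
            lts = ()
        else:
            lts = tuple(raw_lts)

    return SpecimenMeasurement(
        specimen_id=sid, period=period, degree=degree,
        fal=_parse_cell(cell("FAL"), "FAL", row_no),
        pgl=_parse_cell(cell("PGL"), "PGL", row_no),
        orl=_parse_cell(cell("ORL"), "ORL", row_no),
        lts=lts,
        pyl=_parse_cell(cell("PYL"), "PYL", row_no),
    )


def _fmt(value) -> str:
    return "" if value is None else repr(float(value))


def save_specimens(specimens: Iterable[SpecimenMeasurement], path) -> None:
    """Write specimens in the CSV dialect; ``repr`` floats round-trip exactly."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for s in specimens:
            lts_cells = [_fmt(v) for v in s.lts]
            lts_cells += [""] * (HOLASPID_SEGMENTS - len(lts_cells))
            writer.writerow([
                s.specimen_id, s.period,
                "" if s.degree is None else str(s.degree),
                _fmt(s.fal), _fmt(s.pgl), _fmt(s.orl), *lts_cells, _fmt(s.pyl),
            ])


# ---------------------------------------------------------------------------
# Stage summaries


@dataclass
class StageSummary:
    """Per-degree means across specimens.

    ``mean_parts`` maps part names (raw and derived) to arithmetic means over
    specimens where the value is derivable.  ``mean_rls`` / ``mean_rps`` are
    arithmetic means of per-specimen ratios over specimens with a complete
    trunk.  ``trg`` is mean TRL at the next degree over mean TRL here
    (``None`` for the last summarized degree).
    """

    degree: int
    n: int
    mean_parts: Mapping[str, float]
    mean_rls: Optional[tuple]
    mean_rps: Optional[tuple]
    trg: Optional[float] = None


def _mean(values) -> float:
    """Centered compensated mean; exact when all values are identical."""
    values = list(values)
    v0 = values[0]
    return v0 + math.fsum(v - v0 for v in values) / len(values)


def stage_summaries(specimens: Iterable[SpecimenMeasurement],
                    degrees: Optional[Sequence[int]] = None) -> list:
    """Summarize meraspid specimens per degree.

    Degrees with no specimens are omitted with a warning.  TRG is the ratio
    of consecutive stage-mean trunk lengths (cross-sectional data, so a
    ratio of means rather than a mean of per-individual ratios).
    """
    by_degree: dict = {}
    for s in specimens:
        if s.period == MERASPID and s.degree is not None:
            by_degree.setdefault(s.degree, []).append(s)

    if degrees is None:
        degrees = sorted(by_degree)
    out = []
    for d in degrees:
        group = by_degree.get(d, [])
        if not group:
            warnings.warn(f"stage D{d}: no specimens, omitted", stacklevel=2)
            continue
        part_values: dict = {}
        rls_rows, rps_rows = [], []
        names = ["FAL", "PGL", "ORL", "PYL", "CEL", "TRL", "BOL"] + \
                [f"LTS{i}" for i in range(1, d + 1)]
        for s in group:
            for name in names:
                v = derived_value(s, name)
                if v is not None:
                    part_values.setdefault(name, []).append(v)
            der = derive_parts(s)
            if der.rls is not None:
                rls_rows.append(der.rls)
                rps_rows.append(der.rps)
        means = {k: _mean(v) for k, v in part_values.items()}
        out.append(StageSummary(
            degree=d, n=len(group), mean_parts=means,
            mean_rls=tuple(map(_mean, zip(*rls_rows))) if rls_rows else None,
            mean_rps=tuple(map(_mean, zip(*rps_rows))) if rps_rows else None,
        ))

    for cur, nxt in zip(out, out[1:]):
        if (nxt.degree == cur.degree + 1 and "TRL" in cur.mean_parts
                and "TRL" in nxt.mean_parts):
            cur.trg = nxt.mean_parts["TRL"] / cur.mean_parts["TRL"]
    return out


def average_growth_rate(summaries: Sequence[StageSummary], part: str,
                        from_stage: int, to_stage: int) -> float:
    """Geometric per-stage growth factor of a part between two stages."""
    if to_stage <= from_stage:
        raise ValueError(f"to_stage {to_stage} must exceed from_stage {from_stage}")
    by_degree = {s.degree: s for s in summaries}
    try:
        a = by_degree[from_stage].mean_parts[part]
        b = by_degree[to_stage].mean_parts[part]
    except KeyError as exc:
        raise ValueError(f"missing stage or part for AGR: {exc}") from exc
    if a <= 0 or b <= 0:
        raise ValueError(f"non-positive mean {part} in AGR window")
    return (b / a) ** (1.0 / (to_stage - from_stage))


def summaries_to_rows(summaries: Sequence[StageSummary]) -> list:
    """Flatten summaries for CSV export (one dict per stage)."""
    rows = []
    for s in summaries:
        row = {"degree": s.degree, "n": s.n, "TRG": s.trg}
        row.update({k: s.mean_parts[k] for k in sorted(s.mean_parts)})
        if s.mean_rls is not None:
            for i, v in enumerate(s.mean_rls, start=1):
                row[f"RLS{i}"] = v
            for i, v in enumerate(s.mean_rps, start=1):
                row[f"RPS{i}"] = v
        rows.append(row)
    return rows
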