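"""Study-record fixtures and reproduction of the printed summary numbers.

The shipped ``data/subjects.json`` encodes the per-subject study records:
demographics, the stimulation current/charge levels used during and after
insertion, the radiologically shortest-EFND contact, the insertion-phase
position estimates P per EMG channel, and the post-insertion peak-contact
sets at the 75% normalized-amplitude threshold.  The functions below
recompute every printed summary (charge min/max/mean, concordance counts,
agreement subject sets) from those records.

Charge summaries are computed in decimal arithmetic and rounded half-up to
3 decimals, the printed convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import NamedTuple

from .geometry import load_array_catalogue
from .stimulation import charge_from_current, display_round

__all__ = [
    "SubjectFixture",
    "load_subjects",
    "check_charge_conversions",
    "reproduce_charge_summaries",
    "reproduce_table4_concordance",
    "reproduce_table5_agreement",
]


@dataclass(frozen=True)
class SubjectFixture:
    """One subject's study record (S1..S9)."""

    id: str
    age: int
    sex: str
    electrode_type: str
    etiology: str
    insertion_current_cu: float | None
    insertion_charge_qu_printed: float | None
    postinsertion_current_cu: float
    postinsertion_charge_qu_printed: float
    shortest_efnd_contact: int
    p_oculi: int | None
    p_oris: int | None
    peaks_periocular: frozenset[int]
    peaks_perioral: frozenset[int]

    def __post_init__(self) -> None:
        catalogue = load_array_catalogue()
        if self.electrode_type not in catalogue:
            raise ValueError(f"{self.id}: unknown electrode type {self.electrode_type!r}")
        for cu, qu in (
            (self.insertion_current_cu, self.insertion_charge_qu_printed),
            (self.postinsertion_current_cu, self.postinsertion_charge_qu_printed),
        ):
            if cu is not None and qu is not None:
                if abs(charge_from_current(cu) - qu) > 0.001:
                    raise ValueError(
                        f"{self.id}: charge {qu} QU inconsistent with {cu} CU"
                    )


def _fixture_path() -> Path:
    return Path(str(resources.files("cifns").joinpath("data/subjects.json")))


def load_subjects(path: str | Path | None = None) -> list[SubjectFixture]:
    raw = json.loads(Path(path or _fixture_path()).read_text())
    out = []
    for row in raw["subjects"]:
        row = dict(row)
        row["peaks_periocular"] = frozenset(row["peaks_periocular"])
        row["peaks_perioral"] = frozenset(row["peaks_perioral"])
        out.append(SubjectFixture(**row))
    return out


class ConversionCheck(NamedTuple):
    subject: str
    phase: str  # "insertion" | "postinsertion"
    current_cu: float
    charge_qu_printed: float
    charge_qu_computed: float  # half-up rounded to the printed precision
    ok: bool


def check_charge_conversions(
    subjects: list[SubjectFixture] | None = None, tol_qu: float = 0.001
) -> list[ConversionCheck]:
    """Verify the CU -> QU conversion against every recorded pair."""
    subjects = subjects if subjects is not None else load_subjects()
    checks = []
    for s in subjects:
        for phase, cu, qu in (
            ("insertion", s.insertion_current_cu, s.insertion_charge_qu_printed),
            ("postinsertion", s.postinsertion_current_cu, s.postinsertion_charge_qu_printed),
        ):
            if cu is None:
                continue
            computed = display_round(charge_from_current(cu))
            checks.append(
                ConversionCheck(
                    subject=s.id,
                    phase=phase,
                    current_cu=cu,
                    charge_qu_printed=qu,
                    charge_qu_computed=computed,
                    ok=abs(computed - qu) <= tol_qu,
                )
            )
    return checks


class ChargeSummaryReport(NamedTuple):
    """Min/max/mean charge (QU) per phase, half-up rounded to 3 decimals."""

    insertion: tuple[float, float, float]
    postinsertion: tuple[float, float, float]
    n_insertion: int
    n_postinsertion: int


def _decimal_summary(currents: list[float]) -> tuple[float, float, float]:
    qus = [Decimal(repr(cu)) * Decimal("150") / Decimal(1000) for cu in currents]
    mean = sum(qus) / len(qus)
    q = Decimal("0.001")

    def r(d: Decimal) -> float:
        return float(d.quantize(q, rounding=ROUND_HALF_UP))

    return (r(min(qus)), r(max(qus)), r(mean))


def reproduce_charge_summaries(
    subjects: list[SubjectFixture] | None = None,
) -> ChargeSummaryReport:
    """Recompute the charge-level summaries of both measurement phases.

    Insertion: the 8 subjects with a recorded insertion level (S2 has
    none); post-insertion: all 9 subjects.
    """
    subjects = subjects if subjects is not None else load_subjects()
    ins = [s.insertion_current_cu for s in subjects if s.insertion_current_cu is not None]
    post = [s.postinsertion_current_cu for s in subjects]
    return ChargeSummaryReport(
        insertion=_decimal_summary(ins),
        postinsertion=_decimal_summary(post),
        n_insertion=len(ins),
        n_postinsertion=len(post),
    )


class Table4Report(NamedTuple):
    exact_periocular: int
    exact_perioral: int
    match_class: dict[str, dict[str, str]]  # subject -> channel -> class


def _p_match(p: int, shortest: int) -> str:
    if p == shortest:
        return "exact"
    if abs(p - shortest) == 1:
        return "neighbor"
    return "none"


def reproduce_table4_concordance(
    subjects: list[SubjectFixture] | None = None,
) -> Table4Report:
    """Count subjects whose insertion-phase P equals the shortest-EFND contact.

    Subjects without insertion measurements (S2) are excluded.  Odd
    shortest-EFND contacts are unreachable with step size 2; those
    subjects (S8) class as "neighbor" when P is one contact off.
    """
    subjects = subjects if subjects is not None else load_subjects()
    match: dict[str, dict[str, str]] = {}
    for s in subjects:
        if s.p_oculi is None or s.p_oris is None:
            continue
        match[s.id] = {
            "periocular": _p_match(s.p_oculi, s.shortest_efnd_contact),
            "perioral": _p_match(s.p_oris, s.shortest_efnd_contact),
        }
    return Table4Report(
        exact_periocular=sum(m["periocular"] == "exact" for m in match.values()),
        exact_perioral=sum(m["perioral"] == "exact" for m in match.values()),
        match_class=match,
    )


class Table5Report(NamedTuple):
    agreement_periocular: frozenset[str]
    agreement_perioral: frozenset[str]
    count_periocular: int
    count_perioral: int


def reproduce_table5_agreement(
    subjects: list[SubjectFixture] | None = None,
) -> Table5Report:
    """Subjects whose post-insertion peak-contact set contains the
    shortest-EFND contact, per EMG channel."""
    subjects = subjects if subjects is not None else load_subjects()
    oculi = frozenset(
        s.id for s in subjects if s.shortest_efnd_contact in s.peaks_periocular
    )
    oris = frozenset(
        s.id for s in subjects if s.shortest_efnd_contact in s.peaks_perioral
    )
    return Table5Report(
        agreement_periocular=oculi,
        agreement_perioral=oris,
        count_periocular=len(oculi),
        count_perioral=len(oris),
    )
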