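"""Chemical-shift-perturbation (CSP) mapping from HSQC peak lists.

Given apo and bound amide peak lists, compute per-residue combined
chemical-shift perturbations

    quadrature:  Δδ = sqrt((Δ¹H)² + (w_N·Δ¹⁵N)²)      (field standard)
    abs_sum:     Δδ = |Δ¹H| + w_N·|Δ¹⁵N|

with nitrogen weight w_N = 0.25 by default, plus intensity losses
ΔIntensity = 1 − Int_i/Int_0, and classify residues against mean/SD
thresholds of the Δδ profile: ``orange`` for [mean, mean+SD),
``red`` for [mean+SD, mean+2SD), ``above_2sd`` beyond, the scheme used to
color interface maps of chemokine–lectin HSQC titrations. The SD is the
sample standard deviation (n−1).

Peak lists use a Sparky-style whitespace-delimited dialect::

    K27N-H   120.512    8.231    1.03e+06

column 1 the assignment «one-letter»«number»N-H, column 2 the ¹⁵N shift
(ppm), column 3 the ¹H shift (ppm), optional column 4 an intensity.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "PeakList",
    "PeakPair",
    "CSPProfile",
    "PeakListFormatError",
    "match_peaks",
    "compute_csp",
    "classify_residues",
    "summarize_mean_csp",
    "interface_residues",
    "CATEGORY_ORDER",
    "DEFAULT_NITROGEN_WEIGHT",
]

DEFAULT_NITROGEN_WEIGHT = 0.25

#: classification categories from weakest to strongest perturbation
CATEGORY_ORDER = ("excluded", "below_mean", "orange", "red", "above_2sd")
_CATEGORY_RANK = {c: i for i, c in enumerate(CATEGORY_ORDER)}

_ASSIGNMENT_RE = re.compile(r"^([A-Z])(\d+)N-H$")


class PeakListFormatError(ValueError):
    """Raised for malformed or inconsistent peak-list content."""


@dataclass(frozen=True)
class Peak:
    """One assigned amide resonance."""

    aa: str
    number: int
    shift_n: float   # ¹⁵N ppm
    shift_h: float   # ¹H ppm
    intensity: float | None = None

    @property
    def assignment(self) -> str:
        return f"{self.aa}{self.number}N-H"


class PeakList:
    """An ordered collection of assigned peaks from one HSQC spectrum."""

    def __init__(self, peaks: Iterable[Peak], name: str = ""):
        self.peaks: tuple[Peak, ...] = tuple(peaks)
        self.name = name

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def by_assignment(self) -> dict[str, Peak]:
        """Map assignment label -> peak; duplicate assignments are an error."""
        out: dict[str, Peak] = {}
        for p in self.peaks:
            if p.assignment in out:
                raise PeakListFormatError(
                    f"duplicate assignment {p.assignment} in peak list "
                    f"{self.name or '<unnamed>'}"
                )
            out[p.assignment] = p
        return out

    def write(self, path: str | Path) -> None:
        lines = []
        for p in self.peaks:
            row = f"{p.assignment:<12s}{p.shift_n:10.3f}{p.shift_h:10.3f}"
            if p.intensity is not None:
                row += f"  {p.intensity:.6e}"
            lines.append(row)
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path, name: str | None = None) -> "PeakList":
        peaks = []
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.lower().startswith("assignment"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise PeakListFormatError(
                    f"{path}: line {lineno}: expected ≥3 columns, got {len(fields)}"
                )
            m = _ASSIGNMENT_RE.match(fields[0])
            if not m:
                raise PeakListFormatError(
                    f"{path}: line {lineno}: bad assignment {fields[0]!r} "
                    "(expected e.g. K27N-H)"
                )
            try:
                shift_n = float(fields[1])
                shift_h = float(fields[2])
                intensity = float(fields[3]) if len(fields) > 3 else None
            except ValueError as exc:
                raise PeakListFormatError(
                    f"{path}: line {lineno}: non-numeric field ({exc})"
                ) from None
            peaks.append(Peak(m.group(1), int(m.group(2)), shift_n, shift_h, intensity))
        return cls(peaks, name=name or Path(path).stem)


@dataclass(frozen=True)
class PeakPair:
    """Apo/bound pairing of one residue's amide peak.

    Shift differences are bound − apo. Unmatched pairs (residue present in
    only one list) carry no shift or intensity values and are excluded from
    all statistics.
    """

    number: int
    aa: str
    delta_h: float = math.nan   # Δ¹H ppm
    delta_n: float = math.nan   # Δ¹⁵N ppm
    int_0: float | None = None  # apo intensity
    int_i: float | None = None  # bound intensity
    matched: bool = True


def match_peaks(apo: PeakList, bound: PeakList) -> list[PeakPair]:
    """Pair apo and bound peaks by assignment label.

    Residues present in only one list come back with ``matched=False`` and
    enter no statistic downstream. Matching is purely label-based — there
    is deliberately no chemical-shift nearest-neighbour fallback, because a
    silent mis-match is worse than an explicit unmatched flag.
    """
    apo_map = apo.by_assignment()
    bound_map = bound.by_assignment()
    pairs: list[PeakPair] = []
    for label in sorted(set(apo_map) | set(bound_map),
                        key=lambda s: int(_ASSIGNMENT_RE.match(s).group(2))):
        m = _ASSIGNMENT_RE.match(label)
        aa, number = m.group(1), int(m.group(2))
        a = apo_map.get(label)
        b = bound_map.get(label)
        if a is None or b is None:
            present = a or b
            pairs.append(PeakPair(number=number, aa=aa, matched=False,
                                  int_0=a.intensity if a else None,
                                  int_i=b.intensity if b else None))
            continue
        pairs.append(
            PeakPair(
                number=number,
                aa=aa,
                delta_h=b.shift_h - a.shift_h,
                delta_n=b.shift_n - a.shift_n,
                int_0=a.intensity,
                int_i=b.intensity,
            )
        )
    return pairs


@dataclass
class CSPProfile:
    """Per-residue Δδ / ΔIntensity profile with interface categories.

    ``table`` is indexed by residue number with columns ``aa``, ``d1H``,
    ``d15N``, ``ddelta``, ``dintensity``, ``category``, ``matched``.
    ``mean`` and ``sd`` (sample SD, n−1) are computed over matched residues
    only. ``combine`` records which Δδ rule produced the profile.
    """

    table: pd.DataFrame
    w_n: float
    combine: str
    mean: float
    sd: float
    name: str = ""

    @property
    def matched(self) -> pd.DataFrame:
        return self.table[self.table["matched"]]

    @property
    def n_matched(self) -> int:
        return int(self.table["matched"].sum())

    def categories(self) -> pd.Series:
        return self.table["category"]

    def write_tsv(self, path: str | Path) -> None:
        out = self.table.reset_index().rename(columns={"index": "residue"})
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _combine_shifts(d_h: np.ndarray, d_n: np.ndarray, w_n: float, combine: str) -> np.ndarray:
    if combine == "quadrature":
        return np.sqrt(d_h ** 2 + (w_n * d_n) ** 2)
    if combine == "abs_sum":
        return np.abs(d_h) + w_n * np.abs(d_n)
    raise ValueError(f"unknown combine rule {combine!r} (quadrature|abs_sum)")


def compute_csp(
    pairs: Sequence[PeakPair],
    w_n: float = DEFAULT_NITROGEN_WEIGHT,
    combine: str = "quadrature",
    name: str = "",
) -> CSPProfile:
    """Compute the per-residue Δδ and ΔIntensity profile.

    Requires at least 5 matched pairs (an SD over fewer residues is not a
    meaningful threshold basis). Residues with Int_0 = 0 get a flagged,
    undefined ΔIntensity and are excluded from intensity statistics only.
    """
    matched = [p for p in pairs if p.matched]
    if len(matched) < 5:
        raise ValueError(
            f"need ≥5 matched peak pairs to form a profile, got {len(matched)}"
        )
    rows = {}
    for p in sorted(pairs, key=lambda q: q.number):
        if p.matched:
            ddelta = float(_combine_shifts(
                np.asarray(p.delta_h), np.asarray(p.delta_n), w_n, combine))
            if p.int_0 is not None and p.int_i is not None:
                dint = math.nan if p.int_0 == 0 else 1.0 - p.int_i / p.int_0
            else:
                dint = math.nan
            rows[p.number] = (p.aa, p.delta_h, p.delta_n, ddelta, dint, "unclassified", True)
        else:
            rows[p.number] = (p.aa, math.nan, math.nan, math.nan, math.nan, "excluded", False)
    table = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["aa", "d1H", "d15N", "ddelta", "dintensity", "category", "matched"],
    )
    table.index.name = "residue"
    vals = table.loc[table["matched"], "ddelta"]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return CSPProfile(table=table, w_n=w_n, combine=combine, mean=mean, sd=sd, name=name)


def classify_residues(profile: CSPProfile) -> CSPProfile:
    """Fill mean/SD-threshold categories into a computed profile.

    With m = mean(Δδ) and s = sample SD(Δδ) over matched residues:
    ``orange`` ⇔ Δδ ∈ [m, m+s); ``red`` ⇔ Δδ ∈ [m+s, m+2s); ``above_2sd``
    ⇔ Δδ ≥ m+2s; ``below_mean`` otherwise. Unmatched residues stay
    ``excluded``. Degenerate profile (SD = 0): everything below_mean except
    exact-mean ties at a nonzero mean, which are orange (an all-zero
    profile has no perturbation to report at all).
    """
    table = profile.table.copy()
    m, s = profile.mean, profile.sd
    cats = []
    for matched, dd in zip(table["matched"], table["ddelta"]):
        if not matched:
            cats.append("excluded")
        elif s == 0:
            cats.append("orange" if (dd == m and m > 0) else "below_mean")
        elif dd >= m + 2 * s:
            cats.append("above_2sd")
        elif dd >= m + s:
            cats.append("red")
        elif dd >= m:
            cats.append("orange")
        else:
            cats.append("below_mean")
    table["category"] = cats
    return CSPProfile(table=table, w_n=profile.w_n, combine=profile.combine,
                      mean=m, sd=s, name=profile.name)


def interface_residues(profile: CSPProfile, min_category: str = "red") -> frozenset[int]:
    """Residues at or above ``min_category`` (orange|red|above_2sd)."""
    if min_category not in ("orange", "red", "above_2sd"):
        raise ValueError(f"min_category must be orange|red|above_2sd, got {min_category!r}")
    rank = _CATEGORY_RANK[min_category]
    sel = profile.table["category"].map(
        lambda c: _CATEGORY_RANK.get(c, -1) >= rank)
    return frozenset(int(i) for i in profile.table.index[sel])


def summarize_mean_csp(profiles: Mapping[str, CSPProfile]) -> pd.DataFrame:
    """Sequence-averaged Δδ per profile, sorted descending.

    A larger sequence-averaged Δδ indicates a stronger intermolecular
    interaction, the comparison logic used to order binding-site variants.
    All profiles must share the same combine rule and nitrogen weight.
    """
    if not profiles:
        raise ValueError("no profiles given")
    rules = {(p.combine, p.w_n) for p in profiles.values()}
    if len(rules) > 1:
        raise ValueError(
            f"profiles mix combine rules / nitrogen weights: {sorted(rules)}"
        )
    rows = [
        {"name": name, "mean_ddelta": p.mean, "n_residues": p.n_matched}
        for name, p in profiles.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values("mean_ddelta", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
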