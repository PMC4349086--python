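"""Per-sex ranking and top/bottom selection on relative wing size.

Works on the measurement table produced by the analysis pipeline (one
row per fly, keyed by well index).  The selection criterion is a ratio
of measured traits, by default wing area over shoulder width squared -
an area over a length squared, hence dimensionless and insensitive to
overall body size.  Excluded wells (damaged wings, double occupancy)
and unknown-sex flies never enter the ranking.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_CRITERION_RE = re.compile(
    r"^\s*(?P<num>\w+)\s*/\s*(?P<den>\w+)\s*(?:\^\s*(?P<exp>[\d.]+))?\s*$"
)


@dataclass
class Criterion:
    numerator: str
    denominator: str
    exponent: float = 1.0

    @classmethod
    def parse(cls, text: str) -> "Criterion":
        """Parse e.g. ``wa/sw^2`` or ``wl/iod``."""
        m = _CRITERION_RE.match(text)
        if not m:
            raise ValueError(f"cannot parse criterion {text!r}")
        return cls(
            numerator=m.group("num"),
            denominator=m.group("den"),
            exponent=float(m.group("exp") or 1.0),
        )

    def __str__(self) -> str:
        exp = "" if self.exponent == 1.0 else f"^{self.exponent:g}"
        return f"{self.numerator}/{self.denominator}{exp}"


@dataclass
class SelectionResult:
    criterion: Criterion
    selected_top: dict[str, list[int]] = field(default_factory=dict)
    selected_bottom: dict[str, list[int]] = field(default_factory=dict)

    def table(self, scores: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for sex in sorted(self.selected_top):
            for group, wells in (
                ("top", self.selected_top[sex]),
                ("bottom", self.selected_bottom[sex]),
            ):
                for w in wells:
                    rec = scores[scores.well_index == w].iloc[0]
                    rows.append(
                        {
                            "well_index": int(w),
                            "fly_id": rec.fly_id,
                            "sex": sex,
                            "score": float(rec.score),
                            "group": group,
                        }
                    )
        return pd.DataFrame(rows, columns=["well_index", "fly_id", "sex", "score", "group"])


_TRAIT_COLUMNS = {
    "wa": "wa_px2",
    "wl": "wl_px",
    "ww": "ww_px",
    "sw": "sw_px",
    "iod": "iod_px",
}


def _trait(records: pd.DataFrame, name: str) -> pd.Series:
    col = _TRAIT_COLUMNS.get(name, name)
    if col not in records.columns:
        raise KeyError(f"trait {name!r} (column {col!r}) not in records")
    return records[col]


def relative_wing_size(records: pd.DataFrame, criterion: Criterion) -> pd.Series:
    """Score each fly; rows with missing or nonpositive traits get NaN."""
    num = _trait(records, criterion.numerator).astype(float)
    den = _trait(records, criterion.denominator).astype(float)
    score = num / den**criterion.exponent
    bad = ~np.isfinite(score) | (den <= 0) | (num <= 0)
    if bad.any():
        log.warning("%d record(s) skipped: missing or nonpositive traits", bad.sum())
    return score.where(~bad)


def apply_exclusions(
    records: pd.DataFrame, exclusion_csv: str | Path | None
) -> pd.DataFrame:
    """Flag wells listed in the exclusion CSV (columns well_index, reason)."""
    records = records.copy()
    if "excluded" not in records.columns:
        records["excluded"] = False
        records["exclusion_reason"] = ""
    if exclusion_csv is None:
        return records
    table = pd.read_csv(exclusion_csv)
    for _, row in table.iterrows():
        well = int(row["well_index"])
        hit = records.well_index == well
        if not hit.any():
            log.warning("exclusion for unknown well %d ignored", well)
            continue
        records.loc[hit, "excluded"] = True
        records.loc[hit, "exclusion_reason"] = str(row.get("reason", "excluded"))
    return records


def select_extremes(
    records: pd.DataFrame,
    n_top: int,
    n_bottom: int,
    criterion: Criterion | str = "wa/sw^2",
) -> tuple[SelectionResult, pd.DataFrame]:
    """Rank per sex and pick the ``n_top`` largest / ``n_bottom`` smallest.

    Excluded and unknown-sex flies are dropped before ranking.  Ties
    break on fly_id so reruns give identical output.  Asking for more
    flies than available selects everything with a warning.
    """
    if isinstance(criterion, str):
        criterion = Criterion.parse(criterion)
    work = records.copy()
    if "excluded" not in work.columns:
        work["excluded"] = False
    work = work[(~work.excluded) & (work.sex.isin(["male", "female"]))]
    work = work.assign(score=relative_wing_size(work, criterion))
    work = work[np.isfinite(work.score)]
    result = SelectionResult(criterion=criterion)
    for sex, grp in work.groupby("sex"):
        grp = grp.sort_values(
            ["score", "fly_id"], ascending=[False, True], kind="mergesort"
        )
        if n_top + n_bottom > len(grp):
            log.warning(
                "%s: requested %d flies but only %d available; selecting all",
                sex,
                n_top + n_bottom,
                len(grp),
            )
        top = grp.head(n_top)
        bottom = grp.iloc[len(top) :].tail(n_bottom)
        result.selected_top[sex] = [int(w) for w in top.well_index]
        result.selected_bottom[sex] = [int(w) for w in bottom.well_index[::-1]]
    return result, work[["well_index", "fly_id", "sex", "score"]]
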