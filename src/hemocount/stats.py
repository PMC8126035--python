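"""Group comparison of per-image hemocyte counts.

One-way (fixed-effects) ANOVA on the raw counts, followed by the
Tukey–Kramer studentized-range test for pairwise mean differences with the
unequal-n correction SE_ij = sqrt(MSW/2 * (1/n_i + 1/n_j)).  Each image is
one observation within its group.  Probabilities come from scipy's F and
studentized-range distributions.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateVarianceError, ValidationError

__all__ = [
    "CountTable",
    "AnovaResult",
    "TukeyResult",
    "anova_oneway",
    "one_way_anova",
    "tukey_kramer",
    "density_per_area",
]


@dataclass
class CountTable:
    """Per-image hemocyte counts with group labels and field area.

    Thin wrapper over a DataFrame with columns
    ``image_id, group, count, field_area_mm2``.
    """

    frame: pd.DataFrame

    REQUIRED = ("image_id", "group", "count")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.frame)
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"count table missing column {col!r}")
        if (df["count"] < 0).any():
            raise ValidationError("counts must be non-negative")
        if not np.array_equal(df["count"], df["count"].astype(int)):
            raise ValidationError("counts must be integers")
        if "field_area_mm2" not in df.columns:
            df = df.assign(field_area_mm2=np.nan)
        self.frame = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "CountTable":
        return cls(
            pd.DataFrame(
                records, columns=["image_id", "group", "count", "field_area_mm2"]
            )
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "CountTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def groups(self) -> dict[str, np.ndarray]:
        """Counts per group, in group label order of first appearance."""
        out: dict[str, np.ndarray] = {}
        for g in self.frame["group"].unique():
            out[str(g)] = self.frame.loc[
                self.frame["group"] == g, "count"
            ].to_numpy(dtype=float)
        return out


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    grand_mean: float
    ss_between: float
    ss_within: float
    ms_within: float

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p": self.p,
            "grand_mean": self.grand_mean,
            "ss_between": self.ss_between,
            "ss_within": self.ss_within,
            "groups": {
                g: {
                    "n": self.group_ns[g],
                    "mean": self.group_means[g],
                    "sd": self.group_sds[g],
                }
                for g in self.group_means
            },
        }


@dataclass
class TukeyResult:
    alpha: float
    pairs: list[dict] = field(default_factory=list)

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [(p["group_i"], p["group_j"]) for p in self.pairs if p["significant"]]

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "pairs": self.pairs}


def _validate_groups(groups: dict[str, np.ndarray]) -> None:
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    for g, x in groups.items():
        if len(x) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 observations")


def anova_oneway(groups: dict[str, np.ndarray]) -> AnovaResult:
    """Classical one-way ANOVA from a dict of group -> observations."""
    _validate_groups(groups)
    data = {g: np.asarray(x, dtype=float) for g, x in groups.items()}
    all_x = np.concatenate(list(data.values()))
    if np.ptp(all_x) == 0:
        raise DegenerateVarianceError(
            "all observations identical; ANOVA undefined"
        )
    k = len(data)
    N = all_x.size
    grand = float(all_x.mean())
    ssb = float(sum(len(x) * (x.mean() - grand) ** 2 for x in data.values()))
    ssw = float(sum(((x - x.mean()) ** 2).sum() for x in data.values()))
    dfb, dfw = k - 1, N - k
    if ssw == 0:
        raise DegenerateVarianceError("zero within-group variance; F undefined")
    msb, msw = ssb / dfb, ssw / dfw
    F = msb / msw
    p = float(sps.f.sf(F, dfb, dfw))
    return AnovaResult(
        F=F,
        df_between=dfb,
        df_within=dfw,
        p=p,
        group_means={g: float(x.mean()) for g, x in data.items()},
        group_sds={g: float(x.std(ddof=1)) for g, x in data.items()},
        group_ns={g: int(x.size) for g, x in data.items()},
        grand_mean=grand,
        ss_between=ssb,
        ss_within=ssw,
        ms_within=msw,
    )


def one_way_anova(table: CountTable) -> AnovaResult:
    """One-way ANOVA on a count table (one observation per image)."""
    return anova_oneway(table.groups())


def tukey_kramer(table: CountTable, alpha: float = 0.05) -> TukeyResult:
    """Tukey–Kramer pairwise comparisons on a count table.

    For every pair (i, j): SE = sqrt(MSW/2 * (1/n_i + 1/n_j)),
    q = |mean_i - mean_j| / SE, adjusted p from the studentized-range
    distribution with (k, df_within); flagged significant at ``alpha``.
    With balanced groups the Kramer SE reduces to the classical Tukey HSD.
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha={alpha} outside (0, 1)")
    an = one_way_anova(table)
    k = len(an.group_means)
    result = TukeyResult(alpha=alpha)
    for gi, gj in itertools.combinations(an.group_means, 2):
        ni, nj = an.group_ns[gi], an.group_ns[gj]
        diff = an.group_means[gi] - an.group_means[gj]
        se = float(np.sqrt(an.ms_within / 2.0 * (1.0 / ni + 1.0 / nj)))
        q = abs(diff) / se
        p_adj = float(sps.studentized_range.sf(q, k, an.df_within))
        p_adj = min(max(p_adj, 0.0), 1.0)
        result.pairs.append(
            {
                "group_i": gi,
                "group_j": gj,
                "mean_diff": diff,
                "se": se,
                "q": q,
                "p_adj": p_adj,
                "significant": bool(p_adj < alpha),
            }
        )
    return result


def density_per_area(table: CountTable) -> CountTable:
    """Add a hemocytes-per-mm^2 column (count / field_area_mm2)."""
    df = table.frame.copy()
    area = df["field_area_mm2"]
    if area.isna().any() or (area <= 0).any():
        raise ValidationError("field_area_mm2 must be present and positive")
    df["density_per_mm2"] = df["count"] / area
    out = CountTable.__new__(CountTable)
    out.frame = df
    return out


def stats_report(
    table: CountTable, alpha: float = 0.05, path: str | Path | None = None
) -> dict:
    """ANOVA + Tukey–Kramer + group summary, optionally written as JSON."""
    an = one_way_anova(table)
    tk = tukey_kramer(table, alpha=alpha)
    doc = {"anova": an.to_dict(), "tukey_kramer": tk.to_dict()}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
    return doc
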