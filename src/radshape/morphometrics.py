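"""Landmark morphometrics of the distal radius.

Six indicators per subject: four inter-landmark distances (AB, bc, AC, CD,
in mm) and two angles against the radius long axis (ALF: lunate-facet
line; ASR: sigmoid-notch-midpoint-to-styloid line; degrees).  A rule-based
classifier mirrors the clinical criteria (dorsal angulation > 20 deg ->
Colles-type, volar > 20 deg -> Smith-type, articular displacement > 2 mm ->
Barton-type), and ``group_compare`` runs the standard assumption checks
(Shapiro-Wilk, Levene) plus one-way ANOVA with Tukey HSD post hoc tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import RegistrationError, ValidationError
from .io import LandmarkSet, PointCloud

INDICATORS = ("AB", "bc", "AC", "CD", "ALF", "ASR")


@dataclass
class MorphometricProfile:
    AB: float
    bc: float
    AC: float
    CD: float
    ALF: float
    ASR: float

    def __post_init__(self):
        for name in ("AB", "bc", "AC", "CD"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"distance {name} must be positive")
        for name in ("ALF", "ASR"):
            if not 0 <= getattr(self, name) <= 180:
                raise ValidationError(f"angle {name} must lie in [0, 180] deg")

    def as_dict(self):
        return {k: float(getattr(self, k)) for k in INDICATORS}


@dataclass
class RuleCriteria:
    """Clinical thresholds for the rule-based fracture typing."""

    dorsal_angulation_deg: float = 20.0
    volar_angulation_deg: float = 20.0
    articular_displacement_mm: float = 2.0

    def __post_init__(self):
        if min(self.dorsal_angulation_deg, self.volar_angulation_deg,
               self.articular_displacement_mm) <= 0:
            raise ValidationError("criteria thresholds must be positive")


def long_axis(cloud: PointCloud, distal_hint) -> np.ndarray:
    """First principal axis of the cloud, oriented toward ``distal_hint``."""
    pts = cloud.points
    c = pts.mean(axis=0)
    centered = pts - c
    cov = centered.T @ centered / len(pts)
    vals, vecs = np.linalg.eigh(cov)
    if vals[2] <= 0 or (vals[2] - vals[0]) / vals[2] < 1e-9:
        raise RegistrationError("cloud is isotropic; long axis undefined")
    axis = vecs[:, 2]
    hint = np.asarray(distal_hint, dtype=np.float64).reshape(3)
    if axis @ (hint - c) < 0:
        axis = -axis
    return axis


def _angle_deg(u, v) -> float:
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValidationError("zero-length direction in angle measurement")
    return float(np.degrees(np.arccos(np.clip(u @ v / (nu * nv), -1.0, 1.0))))


def measure_profile(landmarks: LandmarkSet, axis, lunate_facet_line
                    ) -> MorphometricProfile:
    """Compute the six indicators.

    ``lunate_facet_line`` is a pair of 3-D points on the lunate facet crest
    (supplied, not detected).  ``axis`` is the oriented radius long axis.
    """
    a, b, c, d = landmarks.A, landmarks.B, landmarks.C, landmarks.D
    p0, p1 = (np.asarray(p, float).reshape(3) for p in lunate_facet_line)
    if np.allclose(p0, p1):
        raise ValidationError("lunate facet line has zero length")
    alf = _angle_deg(p1 - p0, axis)
    asr = _angle_deg(c - (a + b) / 2.0, axis)
    return MorphometricProfile(
        AB=float(np.linalg.norm(a - b)),
        bc=float(np.linalg.norm(b - c)),
        AC=float(np.linalg.norm(a - c)),
        CD=float(np.linalg.norm(c - d)),
        ALF=alf, ASR=asr)


def classify_by_rule(dorsal_angulation_deg: float, displacement_mm: float,
                     criteria: RuleCriteria | None = None) -> str:
    """Rule-based fracture typing.

    Sign convention: positive angulation = dorsal, negative = volar.
    Articular displacement takes precedence (it is the defining feature of
    a Barton-type injury), then the angulation rules.
    """
    criteria = criteria or RuleCriteria()
    if not np.isfinite([dorsal_angulation_deg, displacement_mm]).all():
        raise ValidationError("angulation/displacement must be finite")
    if displacement_mm > criteria.articular_displacement_mm:
        return "barton"
    if dorsal_angulation_deg > criteria.dorsal_angulation_deg:
        return "colles"
    if dorsal_angulation_deg < -criteria.volar_angulation_deg:
        return "smith"
    return "normal"


def profiles_to_frame(profiles, labels) -> pd.DataFrame:
    """Stack per-subject profiles into a DataFrame with a 'group' column."""
    rows = [p.as_dict() for p in profiles]
    df = pd.DataFrame(rows)
    df["group"] = list(labels)
    return df


@dataclass
class GroupComparison:
    anova: pd.DataFrame      # per indicator: Levene, ANOVA F/p, stars
    shapiro: pd.DataFrame    # per (indicator, group): W, p
    tukey: dict              # indicator -> pairwise DataFrame


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def anova_oneway(groups) -> tuple[float, int, int, float]:
    """One-way ANOVA from the definitional sum-of-squares decomposition.

    Returns (F, df_between, df_within, p).
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("ANOVA needs >= 2 groups with >= 2 values each")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(all_vals) - len(groups)
    if ss_within == 0.0:
        f = 0.0 if ss_between == 0.0 else np.inf
    else:
        f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return float(f), df1, df2, p


def group_compare(data: pd.DataFrame, group_col: str = "group",
                  conf_level: float = 0.95) -> GroupComparison:
    """Assumption checks, one-way ANOVA and Tukey HSD per indicator column.

    ``data`` holds one numeric column per indicator plus a group column.
    Groups with fewer than 2 subjects are dropped with a warning.
    """
    if group_col not in data.columns:
        raise ValidationError(f"missing group column {group_col!r}")
    counts = data[group_col].value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        warnings.warn(f"excluding groups with < 2 subjects: {small}")
        data = data[~data[group_col].isin(small)]
    group_names = list(dict.fromkeys(data[group_col]))
    if len(group_names) < 2:
        raise ValidationError("need at least 2 groups with >= 2 subjects")
    indicators = [c for c in data.columns
                  if c != group_col and np.issubdtype(data[c].dtype, np.number)]
    if not indicators:
        raise ValidationError("no numeric indicator columns found")
    anova_rows, shapiro_rows, tukey = [], [], {}
    for ind in indicators:
        groups = [data.loc[data[group_col] == g, ind].to_numpy()
                  for g in group_names]
        for g, vals in zip(group_names, groups):
            if len(vals) >= 3 and np.ptp(vals) > 0:
                w, p = stats.shapiro(vals)
            else:
                w, p = np.nan, np.nan
            shapiro_rows.append({"indicator": ind, "group": g,
                                 "W": w, "p": p})
        lev_f, lev_p = stats.levene(*groups, center="mean")
        f, df1, df2, p = anova_oneway(groups)
        anova_rows.append({"indicator": ind, "levene_F": float(lev_f),
                           "levene_p": float(lev_p), "F": f, "df1": df1,
                           "df2": df2, "p": p, "signif": _stars(p)})
        res = stats.tukey_hsd(*groups)
        ci = res.confidence_interval(confidence_level=conf_level)
        pairs = []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                pairs.append({
                    "group_1": group_names[i], "group_2": group_names[j],
                    "mean_diff": float(groups[i].mean() - groups[j].mean()),
                    "ci_low": float(ci.low[i, j]),
                    "ci_high": float(ci.high[i, j]),
                    "p_adj": float(res.pvalue[i, j]),
                    "signif": _stars(float(res.pvalue[i, j]))})
        tukey[ind] = pd.DataFrame(pairs)
    return GroupComparison(anova=pd.DataFrame(anova_rows),
                           shapiro=pd.DataFrame(shapiro_rows),
                           tukey=tukey)
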