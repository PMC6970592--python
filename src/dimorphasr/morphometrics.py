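"""Normalization, Cohen's d effect sizes, dimorphism classification, t tests.

Each specimen's raw hg-muscle volumes are divided by the summed volume of
the seven measured muscles of that hemithorax, removing overall body-size
differences between sexes and species.  Per species x muscle the
standardized mean difference between sexes (Cohen's d, male - female
convention, Bessel-corrected pooled SD) is thresholded at |d| >= 1.5 to
call the muscle male-enlarged, female-enlarged, or monomorphic.  Under
equal-variance normals, d = 1.5 places one sex's mean at the
100*Phi(1.5) ~ 93.3rd percentile of the other sex's distribution (the U3
overlap statistic), comfortably above the 90th percentile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_data import MUSCLES, HG_MUSCLES, VolumeTable

DIMORPHISM_THRESHOLD = 1.5
STATE_MONO = "monomorphic"
STATE_MALE = "male_enlarged"
STATE_FEMALE = "female_enlarged"
STATE_DIMORPHIC = "dimorphic"  # binary collapse of the two enlarged states

TERNARY = (STATE_MONO, STATE_MALE, STATE_FEMALE)


@dataclass(frozen=True)
class NormalizedProfile:
    """Normalized hg-muscle fractions for one hemithorax."""

    species: str
    sex: str
    specimen_id: str
    norm_volumes: dict  # muscle in hg1..hg4 -> fraction in (0, 1)


@dataclass
class EffectSizeResult:
    species: str
    muscle: str
    n_male: int
    n_female: int
    mean_male: float
    mean_female: float
    sd_male: float
    sd_female: float
    d: float
    state: Optional[str]       # None when flagged (too few samples / degenerate)
    t_stat: float
    p_value: float
    flagged: bool = False
    flag_reason: str = ""


def normalize(table: VolumeTable) -> list[NormalizedProfile]:
    """Per complete record, hg fractions of the seven-muscle total volume.

    Scale-invariant by construction: multiplying every raw volume of a
    hemithorax by a constant leaves each fraction unchanged.
    """
    out = []
    for rec in table.complete_records():
        total = sum(rec.volumes[m] for m in MUSCLES)
        if total <= 0:  # unreachable for complete records; defensive
            continue
        out.append(NormalizedProfile(
            species=rec.species, sex=rec.sex, specimen_id=rec.specimen_id,
            norm_volumes={m: rec.volumes[m] / total for m in HG_MUSCLES}))
    return out


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Signed Cohen's d, (mean(x) - mean(y)) / pooled SD.

    The pooled SD is the Bessel-corrected classical form
    sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)).  Identical constant
    samples give 0; zero pooled SD with differing means gives signed
    infinity (callers flag this as degenerate).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per sample")
    diff = x.mean() - y.mean()
    s2 = (((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1))
          / (len(x) + len(y) - 2))
    sp = math.sqrt(s2)
    if sp == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    return float(diff / sp)


def hedges_g(x: Sequence[float], y: Sequence[float]) -> float:
    """Small-sample-corrected d (optional; not the default classifier input)."""
    n = len(x) + len(y)
    j = 1.0 - 3.0 / (4.0 * n - 9.0)
    return j * cohens_d(x, y)


def t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Classical equal-variance two-sample Student's t, two-sided p.

    Two identical constant samples return (0, 1) by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per sample")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def classify_d(d: float, threshold: float = DIMORPHISM_THRESHOLD) -> str:
    """3-way call from a signed d; the threshold is inclusive (d = 1.5 is
    dimorphic)."""
    if not math.isfinite(d):
        raise ValueError("degenerate effect size cannot be classified")
    if d >= threshold:
        return STATE_MALE
    if d <= -threshold:
        return STATE_FEMALE
    return STATE_MONO


def collapse_binary(state: str) -> str:
    """male_enlarged / female_enlarged -> dimorphic; monomorphic unchanged."""
    return STATE_DIMORPHIC if state in (STATE_MALE, STATE_FEMALE) else STATE_MONO


def u3_percentile(d: float) -> float:
    """Cohen's U3 as a percentage: where the higher-mean sex's mean sits in
    the other sex's distribution, under equal-variance normals."""
    return 100.0 * float(stats.norm.cdf(d))


def effect_sizes(profiles: Iterable[NormalizedProfile], *,
                 muscles: Sequence[str] = HG_MUSCLES,
                 threshold: float = DIMORPHISM_THRESHOLD,
                 min_n: int = 3,
                 hedges: bool = False) -> list[EffectSizeResult]:
    """Per species x muscle effect size, classification, and t test.

    Species x muscle cells with fewer than ``min_n`` specimens in either
    sex, a single sex, or a degenerate (infinite) d are flagged; flagged
    cells carry ``state=None`` and are excluded from downstream
    reconstruction.
    """
    rows = [{"species": p.species, "sex": p.sex,
             **{m: p.norm_volumes[m] for m in muscles}} for p in profiles]
    if not rows:
        return []
    df = pd.DataFrame(rows)
    out: list[EffectSizeResult] = []
    for species, grp in df.groupby("species", sort=True):
        males = grp[grp["sex"] == "male"]
        females = grp[grp["sex"] == "female"]
        for muscle in muscles:
            x = males[muscle].to_numpy()
            y = females[muscle].to_numpy()
            base = dict(species=species, muscle=muscle,
                        n_male=len(x), n_female=len(y))
            if len(x) < max(min_n, 2) or len(y) < max(min_n, 2):
                out.append(EffectSizeResult(
                    **base, mean_male=float(x.mean()) if len(x) else math.nan,
                    mean_female=float(y.mean()) if len(y) else math.nan,
                    sd_male=math.nan, sd_female=math.nan, d=math.nan,
                    state=None, t_stat=math.nan, p_value=math.nan,
                    flagged=True, flag_reason=f"fewer than {min_n} per sex"))
                continue
            d = hedges_g(x, y) if hedges else cohens_d(x, y)
            t, p = t_test(x, y)
            if not math.isfinite(d):
                out.append(EffectSizeResult(
                    **base, mean_male=float(x.mean()), mean_female=float(y.mean()),
                    sd_male=float(x.std(ddof=1)), sd_female=float(y.std(ddof=1)),
                    d=d, state=None, t_stat=t, p_value=p,
                    flagged=True, flag_reason="zero pooled SD, differing means"))
                continue
            out.append(EffectSizeResult(
                **base, mean_male=float(x.mean()), mean_female=float(y.mean()),
                sd_male=float(x.std(ddof=1)), sd_female=float(y.std(ddof=1)),
                d=d, state=classify_d(d, threshold), t_stat=t, p_value=p))
    return out


def effects_frame(effects: Sequence[EffectSizeResult]) -> pd.DataFrame:
    cols = ["species", "muscle", "n_male", "n_female", "mean_male",
            "mean_female", "sd_male", "sd_female", "d", "state",
            "t_stat", "p_value", "flagged", "flag_reason"]
    return pd.DataFrame([{c: getattr(e, c) for c in cols} for e in effects],
                        columns=cols)


def tip_state_map(effects: Sequence[EffectSizeResult], muscle: str, *,
                  mode: str = "ternary") -> dict[str, str]:
    """Species -> state for one muscle, feeding the reconstruction.

    ``mode="binary"`` collapses both enlarged states to ``dimorphic``.
    Flagged species are omitted (they are pruned from the tree).
    """
    if mode not in ("binary", "ternary"):
        raise ValueError(f"unknown mode {mode!r}")
    out = {}
    for e in effects:
        if e.muscle != muscle or e.state is None:
            continue
        out[e.species] = collapse_binary(e.state) if mode == "binary" else e.state
    return out
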