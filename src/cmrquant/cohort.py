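"""Synthetic three-group cohorts for the heart-failure primate study design.

Groups follow the published design: healthy controls, HFpEF (preserved
ejection fraction with diastolic dysfunction) and HFrEF (EF < 65%), ten
subjects each.  Each subject's variables are drawn independently as
Gaussian(mean, sd) from the group's specification; the default
specifications carry the reported group means and SDs for age, hematocrit,
ECV, rest/stress perfusion, EF and the Doppler diastolic indices.  MPR is
not drawn: it is derived per subject as stress/rest perfusion.  Perfusion
variables are absent for HFrEF subjects (stress testing is not performed in
that group for safety), giving the cohort table the same missingness
pattern as the study.

An optional per-group ``age_ecv_slope`` adds a linear age dependence to
ECV (ECV centred at the group mean age) so that age-adjustment statistics
can be exercised on data where the confounding is real.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUPS = ("healthy", "HFpEF", "HFrEF")

#: cohort CSV column order
COHORT_COLUMNS = [
    "subject_id",
    "group",
    "age_years",
    "hct",
    "ecv_pct",
    "perf_rest",
    "perf_stress",
    "mpr",
    "ef_pct",
    "e_a",
    "ep_ap",
    "septal_ep",
    "e_ep",
]


@dataclass(frozen=True)
class GroupSpec:
    """Per-group (mean, sd) pairs for every simulated variable.

    Perfusion entries may be None (variable absent for the group, as for
    HFrEF).  ``hct`` is a fraction; ``ecv`` in percent; perfusion in
    ml/min/g; ``septal_ep`` in cm/s.
    """

    label: str
    n: int
    age: tuple[float, float]
    hct: tuple[float, float]
    ecv: tuple[float, float]
    perf_rest: tuple[float, float] | None
    perf_stress: tuple[float, float] | None
    ef: tuple[float, float]
    e_a: tuple[float, float]
    ep_ap: tuple[float, float]
    septal_ep: tuple[float, float]
    e_ep: tuple[float, float]
    age_ecv_slope: float = 0.0  # percent ECV per year, around the group mean age

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        for name in ("age", "hct", "ecv", "perf_rest", "perf_stress", "ef", "e_a", "ep_ap", "septal_ep", "e_ep"):
            pair = getattr(self, name)
            if pair is None:
                continue
            mean, sd = pair
            if not np.isfinite(mean):
                raise ValueError(f"{name} mean must be finite")
            if sd < 0:
                raise ValueError(f"{name} sd must be nonnegative")


# Reported group means +/- SDs (Hct converted from percent to fraction).
HEALTHY_SPEC = GroupSpec(
    label="healthy",
    n=10,
    age=(9.6, 1.3),
    hct=(0.5140, 0.065),
    ecv=(20.79, 3.65),
    perf_rest=(1.31, 0.20),
    perf_stress=(2.40, 0.34),
    ef=(73.96, 4.55),
    e_a=(1.26, 0.23),
    ep_ap=(1.16, 0.25),
    septal_ep=(9.50, 2.31),
    e_ep=(8.04, 2.2),
)

HFPEF_SPEC = GroupSpec(
    label="HFpEF",
    n=10,
    age=(19.9, 1.4),
    hct=(0.5149, 0.050),
    ecv=(27.06, 3.37),
    perf_rest=(1.05, 0.21),
    perf_stress=(1.28, 0.24),
    ef=(76.64, 8.72),
    e_a=(0.69, 0.03),
    ep_ap=(0.77, 0.16),
    septal_ep=(4.78, 0.77),
    e_ep=(11.49, 1.42),
)

HFREF_SPEC = GroupSpec(
    label="HFrEF",
    n=10,
    age=(16.2, 2.7),
    hct=(0.5083, 0.050),
    ecv=(31.11, 4.50),
    perf_rest=None,
    perf_stress=None,
    ef=(47.99, 8.95),
    e_a=(0.82, 0.22),
    ep_ap=(0.67, 0.12),
    septal_ep=(5.02, 1.54),
    e_ep=(10.1, 2.36),
)

DEFAULT_SPECS = (HEALTHY_SPEC, HFPEF_SPEC, HFREF_SPEC)


def _draw(rng: np.random.Generator, pair: tuple[float, float] | None, n: int) -> np.ndarray:
    if pair is None:
        return np.full(n, np.nan)
    mean, sd = pair
    return rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, float(mean))


def generate_cohort(specs=DEFAULT_SPECS, seed: int | None = None) -> pd.DataFrame:
    """Draw one cohort; reproducible under a fixed seed.

    Hematocrit draws are clipped into (0, 1); perfusion draws are clipped
    to a small positive floor so the derived per-subject MPR = stress/rest
    stays defined.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one group spec")
    rng = np.random.default_rng(seed)
    frames = []
    for spec in specs:
        n = spec.n
        age = _draw(rng, spec.age, n)
        hct = np.clip(_draw(rng, spec.hct, n), 1e-3, 1 - 1e-3)
        ecv = _draw(rng, spec.ecv, n)
        if spec.age_ecv_slope != 0.0:
            ecv = ecv + spec.age_ecv_slope * (age - spec.age[0])
        rest = _draw(rng, spec.perf_rest, n)
        stress = _draw(rng, spec.perf_stress, n)
        if spec.perf_rest is not None:
            rest = np.clip(rest, 1e-3, None)
        if spec.perf_stress is not None:
            stress = np.clip(stress, 1e-3, None)
        with np.errstate(invalid="ignore"):
            mpr = stress / rest
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{spec.label}-{i + 1:02d}" for i in range(n)],
                    "group": spec.label,
                    "age_years": age,
                    "hct": hct,
                    "ecv_pct": ecv,
                    "perf_rest": rest,
                    "perf_stress": stress,
                    "mpr": mpr,
                    "ef_pct": _draw(rng, spec.ef, n),
                    "e_a": np.clip(_draw(rng, spec.e_a, n), 1e-3, None),
                    "ep_ap": np.clip(_draw(rng, spec.ep_ap, n), 1e-3, None),
                    "septal_ep": np.clip(_draw(rng, spec.septal_ep, n), 1e-3, None),
                    "e_ep": np.clip(_draw(rng, spec.e_ep, n), 1e-3, None),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[COHORT_COLUMNS]
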