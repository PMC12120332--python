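"""Individual-level covariates: body condition and tag burden.

Body condition is the residual of an ordinary least-squares regression of
log mass on log fork length, pooled across *all* tagged fish (all rivers
and years), so it measures mass independent of length on a common
allometry.  Tag burden is tag mass as a percentage of body mass in air.
Natural logs are used throughout; residuals are invariant to the log base
up to a constant factor and to unit rescaling of length or mass (those only
shift the intercept).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ConditionModel:
    """Fitted log mass ~ log length allometry and per-fish residuals."""

    intercept: float
    slope: float
    residuals: pd.Series  # indexed like the fitting table; the condition index

    def predict_log_mass(self, fork_length_mm):
        return self.intercept + self.slope * np.log(fork_length_mm)


def body_condition(fish: pd.DataFrame) -> ConditionModel:
    """Fit the pooled length-mass regression and return per-fish condition.

    Requires at least 3 fish with complete, strictly positive biometrics.
    Fish with zero or negative length/mass raise a domain error naming them.
    """
    complete = fish[fish["fork_length_mm"].notna() & fish["mass_g"].notna()]
    bad = complete[(complete["fork_length_mm"] <= 0) | (complete["mass_g"] <= 0)]
    if len(bad):
        ids = bad["fish_id"].tolist() if "fish_id" in bad else bad.index.tolist()
        raise ValueError(f"non-positive length or mass for fish {ids[:10]}")
    if len(complete) < 3:
        raise ValueError(f"need >= 3 fish with complete biometrics, got {len(complete)}")

    x = np.log(complete["fork_length_mm"].to_numpy(dtype=float))
    y = np.log(complete["mass_g"].to_numpy(dtype=float))
    if np.ptp(x) < 1e-12:
        # degenerate design (all lengths identical): flat fit through the mean
        slope, intercept = 0.0, float(y.mean())
    else:
        slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return ConditionModel(
        intercept=float(intercept),
        slope=float(slope),
        residuals=pd.Series(resid, index=complete.index, name="condition"),
    )


def tag_burden(fish) -> pd.Series:
    """Tag mass as a percentage of fish body mass: 100 * tag_mass / mass.

    Missing body mass yields a missing burden (the fish is then excluded
    from the individual-success analysis downstream); non-positive recorded
    mass is a domain error.
    """
    if isinstance(fish, pd.Series):
        fish = fish.to_frame().T
    mass = pd.to_numeric(fish["mass_g"], errors="coerce")
    tag = pd.to_numeric(fish["tag_mass_g"], errors="coerce")
    nonpos = fish[(mass <= 0)]
    if len(nonpos):
        ids = nonpos["fish_id"].tolist() if "fish_id" in nonpos else nonpos.index.tolist()
        raise ValueError(f"non-positive body mass for fish {ids[:10]}")
    out = 100.0 * tag / mass
    out.name = "tag_burden_pct"
    return out
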