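"""Longitudinal trait datasets with a known variance structure.

Each trait value is ``baseline + cow_effect + season_effect + residual``
with independent Gaussian cow effects and residuals, so the variance
fraction explained by the cow grouping (eta squared) has a closed form and
the statistical layer can be tested against designed effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cowtof.stats import season_of_week

#: plausible baseline magnitudes (cm / cm^2 / mm) for the default traits
DEFAULT_BASELINES: dict[str, float] = {
    "HH": 40.0, "DL": 12.0, "DR": 12.0, "VL": 14.0, "VR": 14.0,
    "DPL": 5.0, "APL": 7.0, "DML": 4.0, "AML": 7.0,
    "DPR": 5.0, "APR": 7.0, "DMR": 4.0, "AMR": 7.0,
    "BFT": 10.0,
}


@dataclass
class LongitudinalSimSpec:
    """Design of a simulated herd recording.

    ``cow_sd``, ``resid_sd`` and ``season_effects`` may be scalars/tuples
    (shared by all traits) or per-trait dicts.  The implied eta squared of
    the cow grouping is available in closed form via :meth:`expected_eta2`.
    """

    n_cows: int = 50
    n_weeks: int = 40
    baselines: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    cow_sd: float | dict[str, float] = 1.0
    season_effects: tuple[float, float, float, float] | dict = (0.0, 0.0, 0.0, 0.0)
    resid_sd: float | dict[str, float] = 1.0
    start_iso_week: int = 30
    #: rescale the drawn cow effects to the exact design SD, so the designed
    #: effect size is realised in every dataset rather than only on average
    standardize_cow_effects: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cows < 2:
            raise ValueError("need at least 2 cows")
        if self.n_weeks < 1:
            raise ValueError("need at least 1 week")

    def _per_trait(self, value, trait: str):
        return value[trait] if isinstance(value, dict) else value

    def iso_weeks(self) -> np.ndarray:
        return (self.start_iso_week - 1 + np.arange(self.n_weeks)) % 52 + 1

    def expected_eta2(self, trait: str) -> float:
        """Closed-form eta squared of the cow grouping for one trait.

        Season effects vary within cows (all cows see the same weeks), so
        they add to the within-cow variance together with the residual.
        """
        sc = float(self._per_trait(self.cow_sd, trait))
        se = float(self._per_trait(self.resid_sd, trait))
        eff = self._per_trait(self.season_effects, trait)
        seasons = season_of_week(self.iso_weeks())
        seq = np.array([eff[s - 1] for s in seasons], dtype=float)
        var_season = float(seq.var())
        total = sc**2 + var_season + se**2
        return sc**2 / total if total > 0 else 0.0


def generate_longitudinal_dataset(spec: LongitudinalSimSpec) -> pd.DataFrame:
    """One row per cow and week; columns: identifiers plus the trait values.

    Also carries ``start_<trait>`` columns (the cow's first-week value) as
    the starting-level covariate for the coefficient-of-determination model.
    """
    rng = np.random.default_rng(spec.seed)
    iso = spec.iso_weeks()
    seasons = season_of_week(iso)
    traits = list(spec.baselines)

    rows = {
        "cow_id": np.repeat([f"cow{i:03d}" for i in range(spec.n_cows)], spec.n_weeks),
        "lactation_week": np.tile(np.arange(1, spec.n_weeks + 1), spec.n_cows),
        "iso_week": np.tile(iso, spec.n_cows),
        "season": np.tile(seasons, spec.n_cows),
    }
    df = pd.DataFrame(rows)
    for trait in traits:
        sc = float(spec._per_trait(spec.cow_sd, trait))
        se = float(spec._per_trait(spec.resid_sd, trait))
        eff = spec._per_trait(spec.season_effects, trait)
        cow_eff = rng.normal(0.0, sc, spec.n_cows)
        if spec.standardize_cow_effects and sc > 0 and cow_eff.std() > 0:
            cow_eff = (cow_eff - cow_eff.mean()) * (sc / cow_eff.std())
        resid = rng.normal(0.0, se, (spec.n_cows, spec.n_weeks))
        season_seq = np.array([eff[s - 1] for s in seasons], dtype=float)
        values = (
            spec.baselines[trait]
            + cow_eff[:, None]
            + season_seq[None, :]
            + resid
        )
        df[trait] = values.ravel()
        df[f"start_{trait}"] = np.repeat(values[:, 0], spec.n_weeks)
    return df
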