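"""Reference benchmark scenarios used by the acceptance checks.

These fix the study conditions for the headline performance numbers:

* ``paternal_bias_scenario`` — autosomal cohort large enough to inject
  >= 10,000 de novo events, for checking the 70/30 paternal/maternal
  assignment bias.
* ``x_sensitivity_scenario`` — X-chromosome cohorts at 15x mean depth
  with 1% per-read error, mutation prior 1e-5 and founder
  allele-frequency priors.  250 trios per offspring sex (a
  cohort-scale founder panel of 500 parents, which sets the
  allele-frequency clamp floor) x 100 sites at a 0.1 per-site de novo
  rate give >= 2,000 true de novo trio-sites per sex.  Sites carry no
  inherited variation, mirroring de novo injection at random —
  overwhelmingly monomorphic — genome positions.
"""

from __future__ import annotations

from .evaluate import score_calls
from .pipeline import CallerConfig, call_sites
from .simulate import SimulationConfig, simulate_trios

__all__ = [
    "paternal_bias_scenario",
    "x_sensitivity_scenario",
    "measure_paternal_share",
    "measure_x_sensitivity",
]


def paternal_bias_scenario(seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_trios=20,
        n_sites=2650,
        chromosome="1",
        dnm_rate=0.2,
        paternal_fraction=0.70,
        mean_depth=30,
        seed=seed,
    )


def x_sensitivity_scenario(child_sex: str, seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_trios=250,
        n_sites=100,
        chromosome="X",
        male_fraction=1.0 if child_sex == "male" else 0.0,
        monomorphic_fraction=1.0,
        dnm_rate=0.1,
        paternal_fraction=0.70,
        mean_depth=15,
        error_rate=0.01,
        seed=seed,
    )


def measure_paternal_share(seed: int) -> tuple[float, int]:
    """Realised paternal share (fraction) and de novo count."""
    ds = simulate_trios(paternal_bias_scenario(seed))
    dnms = ds.truth[ds.truth.is_dnm]
    return float((dnms["origin"] == "paternal").mean()), int(len(dnms))


def measure_x_sensitivity(child_sex: str, seed: int) -> tuple[float, int]:
    """Sensitivity tp/(tp+fn) on X de novo sites and the number evaluated."""
    ds = simulate_trios(x_sensitivity_scenario(child_sex, seed))
    result = call_sites(
        ds.sites,
        ds.trios,
        CallerConfig(mu=1e-5, af_source="founders"),
    )
    res = score_calls(result.calls, ds.truth, threshold=0.0)
    return float(res.sensitivity), res.counts.tp + res.counts.fn
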