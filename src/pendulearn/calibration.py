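"""Replicate-study calibration: type-I error and power of the pipeline.

These helpers re-run the whole chain — synthetic cohort, block metrics,
retention contrast, factorial test — across many independently seeded
studies, to measure the operating characteristics of the haptic-rendering
main-effect test on the long-term learning contrast (LTR - BL score):

* with all group effects zeroed, the rejection rate estimates the type-I
  error and should sit near the nominal alpha;
* with the demonstration effect configuration, the rejection rate is the
  power to detect the haptic-rendering learning benefit.

Replicates run at a reduced scale (shorter blocks, 600 Hz) so hundreds of
studies stay affordable; only the phases entering the contrast are
simulated, which is exact because every block draws from its own
counter-based seed.
"""

from __future__ import annotations

from typing import Optional

from .cohort import GroupEffects, generate_study
from .stats import factorial_test, retention_contrast

__all__ = ["hr_rejection_rate", "null_rejection_rate", "hr_effect_power"]

REDUCED_BLOCK_DURATION_S = 10.0
REDUCED_SAMPLE_RATE_HZ = 600.0


def hr_rejection_rate(n_studies: int, effects: GroupEffects,
                      n_per_group: int, first_seed: int = 1,
                      block_duration: float = REDUCED_BLOCK_DURATION_S,
                      sample_rate: float = REDUCED_SAMPLE_RATE_HZ,
                      endpoint: str = "LTR", baseline: str = "BL",
                      metric: str = "score") -> float:
    """Fraction of replicate studies rejecting the HR main effect.

    Studies use seeds ``first_seed .. first_seed + n_studies - 1``.  Each
    study generates its cohort, computes the per-participant
    ``endpoint - baseline`` contrast of ``metric``, runs the factorial test
    battery (ANOVA or Kruskal-Wallis per the normality check) and records
    whether the haptic-rendering main effect is significant at alpha = 0.05.
    """
    rejections = 0
    for seed in range(first_seed, first_seed + n_studies):
        cohort = generate_study(
            n_per_group=n_per_group, effects=effects, seed=seed,
            block_duration=block_duration, sample_rate=sample_rate,
            metrics=(metric,), phases=(baseline, endpoint))
        contrast = retention_contrast(cohort.metrics, metric,
                                      endpoint=endpoint, baseline=baseline)
        results = factorial_test(contrast["value"], contrast["hr_train"],
                                 contrast["ws_train"])
        hr_result = next(r for r in results if r.effect == "HR")
        rejections += hr_result.significant
    return rejections / n_studies


def null_rejection_rate(n_studies: int = 500, n_per_group: int = 4,
                        first_seed: int = 1, **kwargs) -> float:
    """Type-I error of the HR test under zero group effects."""
    return hr_rejection_rate(n_studies, GroupEffects.null(), n_per_group,
                             first_seed=first_seed, **kwargs)


def hr_effect_power(n_studies: int = 200, n_per_group: int = 10,
                    first_seed: int = 1,
                    effects: Optional[GroupEffects] = None,
                    **kwargs) -> float:
    """Power of the HR test under the demonstration effect configuration."""
    if effects is None:
        effects = GroupEffects()
    return hr_rejection_rate(n_studies, effects, n_per_group,
                             first_seed=first_seed, **kwargs)
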