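"""The national-responsibility decision tree.

A species' distribution pattern (local / regional / wide) is crossed
with the comparison of the observed against the expected distribution
proportion. A country holding more of a narrowly distributed species
than its size alone predicts carries the greatest responsibility; a
country where a widespread species is no more than proportionally
present carries only basic responsibility; a country where the species
does not occur carries none.

The pattern x comparison -> class table is configuration data (see
``core_model.DEFAULT_NR_MAPPING``), validated to be monotone in both
arguments, and printed in every run summary.
"""

from __future__ import annotations

from .core_model import (
    AssessmentConfig,
    DistributionPattern,
    ResponsibilityClass,
)


def compare_dp(dp_obs: float, dp_exp: float, cfg: AssessmentConfig) -> bool:
    """Is the observed proportion higher than expected?

    Under the default strict comparison a tie carries no evidence of
    over-representation and resolves to the lower-responsibility branch.
    """
    for name, v in (("dp_obs", dp_obs), ("dp_exp", dp_exp)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
    return dp_obs > dp_exp if cfg.strict_comparison else dp_obs >= dp_exp


def nr_class(
    pattern: DistributionPattern | None,
    higher: bool,
    present_in_focal: bool,
    cfg: AssessmentConfig | None = None,
) -> ResponsibilityClass:
    """Responsibility class for one (species, focal area) pair.

    Absence from the focal area always yields NONE, whatever the
    pattern; otherwise the configured mapping table decides.
    """
    if not present_in_focal:
        return ResponsibilityClass.NONE
    if pattern is None:
        raise ValueError("present species requires a distribution pattern")
    mapping = cfg.nr_mapping if cfg is not None else None
    if mapping is None:
        from .core_model import DEFAULT_NR_MAPPING as mapping  # noqa: F811
    return mapping[(pattern, bool(higher))]
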