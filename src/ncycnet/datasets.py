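"""Reference summary data shipped with the package.

The package emulates a published-style field campaign: N-cycle functional
genes quantified by HT-qPCR in Rwandan pasture soils at two locations over
six timepoints spanning a dry-to-rainy seasonal transition, with
co-occurrence networks intersected by location at each timepoint.  The
printed summary of those six intersection networks (density, observed and
Erdos-Renyi-random clustering coefficient C and average path length L) is
provided here as reference input for recomputing derived quantities —
response ratios, seasonal density summaries — with this package's own
functions.
"""

from __future__ import annotations

import pandas as pd

# timepoint, season, growth_stage, density, c_obs, c_random_mean,
# c_random_sd, l_obs, l_random_mean, l_random_sd
_ROWS = [
    (1, "late_dry", "anthesis", 0.83, 0.89, 0.73, 0.01, 1.17, 1.26, 0.00),
    (2, "late_dry", "regrowth", 0.28, 0.62, 0.30, 0.05, 1.86, 1.83, 0.04),
    (3, "mid_rainy", "anthesis", 0.46, 0.73, 0.44, 0.04, 1.85, 1.56, 0.02),
    (4, "mid_rainy", "regrowth", 0.42, 0.68, 0.47, 0.04, 1.68, 1.53, 0.02),
    (5, "late_rainy", "anthesis", 0.25, 0.46, 0.23, 0.06, 1.86, 2.03, 0.09),
    (6, "late_rainy", "regrowth", 0.38, 0.38, 0.42, 0.15, 1.53, 1.52, 0.06),
]

_COLUMNS = [
    "timepoint",
    "season",
    "growth_stage",
    "density",
    "c_obs",
    "c_random_mean",
    "c_random_sd",
    "l_obs",
    "l_random_mean",
    "l_random_sd",
]


def rwanda_intersection_summary() -> pd.DataFrame:
    """Per-timepoint intersection-network summary of the emulated field
    study (anthesis at odd timepoints, post-harvest regrowth at even)."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)
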