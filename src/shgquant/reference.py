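"""Access to the published reference cohort summary statistics.

The package ships the per-group summary table of a published two-cohort
SHG imaging study (means, SDs, ranges and Ns of F/B and FAV per region,
plus clinical covariate counts) as plain JSON. These printed numbers
serve as inputs to internal-consistency checks: the whole-cohort means
quoted alongside the study's figures must equal the sample-size-
weighted combination of the per-group means, and the categorical-
variable test statistics must be reproducible from the printed counts.
"""

from __future__ import annotations

import json
from importlib import resources

__all__ = ["load_reference_cohort", "pooled_reference_means"]


def load_reference_cohort() -> dict:
    """The shipped per-group reference summary table, as a dict."""
    with resources.files("shgquant.data").joinpath("reference_cohort.json").open() as fh:
        return json.load(fh)


def pooled_reference_means() -> dict[str, float]:
    """Whole-cohort metric means recomputed from the per-group rows.

    Returns sample-size-weighted means keyed ``"<cohort>_<metric>"``
    (e.g. ``"CRC_FB_TSI"``), computed with
    :func:`shgquant.stats.pooled_weighted_mean`.
    """
    from .stats import pooled_weighted_mean

    ref = load_reference_cohort()
    out = {}
    for cohort in ("CRC", "IDC"):
        groups = ref[cohort]["groups"]
        for metric in ("FB_TSI", "FB_TB", "FAV_TSI", "FAV_TB"):
            stats = [
                (g["metrics"][metric]["mean"], g["metrics"][metric]["n_observed"])
                for g in groups.values()
            ]
            out[f"{cohort}_{metric}"] = pooled_weighted_mean(stats)
    return out
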