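"""Bundled worked-example tables for an OECD health-system efficiency study.

Three small published result tables are reproduced here verbatim so that the
ranking, related-factor and convergence rules can be exercised against real
printed numbers without any external data:

* ``EFFICIENCY_SCORES`` — technical-efficiency scores for 29 OECD
  countries (the frontier-stage output, one score per country).
* ``FRONTIER_SUMMARY_ROWS`` — the frontier-stage posterior summary table
  (mean, SD, MC error, 2.5%, median, 97.5%, start, sample size).
* ``INDICATOR_SUMMARY_ROWS`` — the regression-stage posterior summary for
  the intercept and 20 policy indicators (mean, SD, MC error, 2.5%, 97.5%).

They are inputs to tests and the acceptance report, not computed output.
"""

from __future__ import annotations

from bsfareg.diagnostics import PosteriorSummary

__all__ = [
    "EFFICIENCY_SCORES",
    "FRONTIER_SUMMARY_ROWS",
    "INDICATOR_SUMMARY_ROWS",
    "frontier_summaries",
    "indicator_summaries",
]

EFFICIENCY_SCORES: dict[str, float] = {
    "Australia": 0.991,
    "Greece": 0.987,
    "Korea": 0.957,
    "Iceland": 0.955,
    "Mexico": 0.955,
    "Switzerland": 0.953,
    "Sweden": 0.947,
    "Germany": 0.944,
    "Japan": 0.943,
    "France": 0.939,
    "Canada": 0.935,
    "Netherlands": 0.935,
    "Portugal": 0.933,
    "Austria": 0.932,
    "Norway": 0.922,
    "Belgium": 0.917,
    "New Zealand": 0.917,
    "Luxembourg": 0.916,
    "Poland": 0.914,
    "Ireland": 0.911,
    "Finland": 0.908,
    "Spain": 0.905,
    "Denmark": 0.899,
    "Czech Republic": 0.895,
    "United Kingdom": 0.891,
    "Italy": 0.824,
    "Hungary": 0.812,
    "Slovak Republic": 0.808,
    "Turkey": 0.805,
}

# node, mean, sd, mc_error, q2.5, median, q97.5, start, sample
FRONTIER_SUMMARY_ROWS: list[tuple] = [
    ("Constant", 12.713, 1.231, 0.045, 10.713, 11.913, 13.113, 12000, 37500),
    ("GDP", 7.631, 0.226, 0.009, 6.816, 7.126, 7.436, 12000, 37500),
    ("Health expenditure", 1.625, 0.085, 0.002, 1.323, 1.417, 1.671, 12000, 37500),
    ("Education", 0.932, 0.456, 0.015, -0.045, 10.021, 1.524, 12000, 37500),
    ("Tobacco consumption", 1.441, 0.036, 0.001, 0.817, 1.563, 1.971, 12000, 37500),
    ("Alcohol consumption", 0.673, 0.423, 0.007, -0.126, 0.871, 1.320, 12000, 37500),
    ("Fruit and vegetables consumption", 1.273, 0.185, 0.003, 0.871, 1.345, 1.824, 12000, 37500),
    ("Nitrogen oxide emissions", 0.717, 0.167, 0.002, 0.218, 0.894, 1.023, 12000, 37500),
    ("Time", 1.231, 0.027, 0.001, 0.101, 1.321, 1.444, 12000, 37500),
    ("Lambda", 0.128, 0.063, 0.002, 0.071, 0.112, 0.011, 12000, 37500),
]

# variable, mean, sd, mc_error, q2.5, q97.5
INDICATOR_SUMMARY_ROWS: list[tuple] = [
    ("(Intercept)", -0.117, 0.202, 0.0081, -0.278, 0.173),
    ("X1", 0.138, 0.093, 0.0033, -0.041, 0.244),
    ("X2", 0.007, 0.048, 0.0019, -0.047, 0.091),
    ("X3", 0.011, 0.053, 0.0020, -0.045, 0.102),
    ("X4", 0.026, 0.119, 0.0047, -0.141, 0.142),
    ("X5", -0.044, 0.079, 0.0033, -0.159, 0.067),
    ("X6", 0.143, 0.013, 0.0052, 0.026, 0.258),
    ("X7", -0.034, 0.091, 0.0031, -0.118, 0.092),
    ("X8", 0.093, 0.055, 0.0018, 0.021, 0.140),
    ("X9", 0.077, 0.011, 0.0004, 0.005, 0.228),
    ("X10", -0.047, 0.077, 0.0028, -0.127, 0.046),
    ("X11", 0.149, 0.024, 0.0011, 0.012, 0.253),
    ("X12", 0.077, 0.181, 0.0067, -0.135, 0.254),
    ("X13", 0.039, 0.078, 0.0025, -0.067, 0.146),
    ("X14", 0.032, 0.164, 0.0061, -0.100, 0.271),
    ("X15", 0.112, 0.009, 0.0004, 0.062, 0.218),
    ("X16", 0.035, 0.242, 0.0087, -0.193, 0.401),
    ("X17", 0.018, 0.121, 0.0034, -0.152, 0.124),
    ("X18", 0.195, 0.141, 0.0029, -0.109, 0.454),
    ("X19", 0.159, 0.026, 0.0011, 0.028, 0.336),
    ("X20", -0.013, 0.112, 0.0039, -0.212, 0.098),
]


def frontier_summaries() -> list[PosteriorSummary]:
    """Frontier-stage rows as PosteriorSummary objects.

    Two printed medians fall outside their own credible interval (obvious
    typos in the source table); the median is clipped into [q2.5, q97.5]
    and, for the one row whose printed interval is itself inverted, the
    interval endpoints are sorted.  SD and MC error are kept verbatim —
    they are the fields the convergence rule reads.
    """
    out = []
    for node, mean, sd, mce, lo, med, hi, start, sample in FRONTIER_SUMMARY_ROWS:
        lo, hi = min(lo, hi), max(lo, hi)
        med = min(max(med, lo), hi)
        out.append(
            PosteriorSummary(
                node=node, mean=mean, sd=sd, mc_error=mce,
                median=med, q2_5=lo, q97_5=hi,
                n_retained=sample, start=start,
            )
        )
    return out


def indicator_summaries() -> list[PosteriorSummary]:
    """Regression-stage rows as PosteriorSummary objects (median := mean)."""
    return [
        PosteriorSummary(
            node=var, mean=mean, sd=sd, mc_error=mce,
            median=min(max(mean, lo), hi), q2_5=lo, q97_5=hi,
            n_retained=38500, start=9500,
        )
        for var, mean, sd, mce, lo, hi in INDICATOR_SUMMARY_ROWS
    ]
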