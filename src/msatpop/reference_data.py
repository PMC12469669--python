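"""Reported summary statistics of the seven-breed rabbit microsatellite survey.

These are the published per-locus F-statistics (with island-model gene flow
Nm) and the per-breed, per-locus neutrality deviates D for the seven breeds
(BB, WB, RB, JAB, NZW, AR, CH) at the 14-marker panel. They are used as
internal-consistency fixtures: the gene-flow transform, the summary-row
conventions, and the breed-mean conventions can be checked against them
without access to the raw genotypes, which were never deposited.

``None`` encodes a dash in the source tables (suppressed or undefined cell).
"""

from __future__ import annotations

LOCI: tuple[str, ...] = (
    "Sat3", "Sol33", "Sol44", "Sat5",
    "D5Utr4a", "D5Utr4b", "D5Utr4c", "D5Utr4d", "D5Utr4e", "D5Utr4f",
    "D7Utr4a", "D7Utr4b", "D19Utr4a", "D19Utr4b",
)

#: Per-locus FIS, FIT, FST and Nm. Nm is None for D7Utr4b (FST = 0.002,
#: below the stability floor).
FSTATS: dict[str, dict[str, float | None]] = {
    "Sat3":     {"FIS": 0.132,  "FIT": 0.337,  "FST": 0.237, "Nm": 0.805},
    "Sol33":    {"FIS": 0.018,  "FIT": 0.232,  "FST": 0.217, "Nm": 0.902},
    "Sol44":    {"FIS": -0.079, "FIT": -0.027, "FST": 0.048, "Nm": 4.958},
    "Sat5":     {"FIS": 0.027,  "FIT": 0.090,  "FST": 0.065, "Nm": 3.596},
    "D5Utr4a":  {"FIS": -0.420, "FIT": -0.103, "FST": 0.223, "Nm": 0.871},
    "D5Utr4b":  {"FIS": 0.665,  "FIT": 0.908,  "FST": 0.725, "Nm": 0.095},
    "D5Utr4c":  {"FIS": -0.155, "FIT": 0.166,  "FST": 0.278, "Nm": 0.649},
    "D5Utr4d":  {"FIS": -0.693, "FIT": -0.116, "FST": 0.341, "Nm": 0.483},
    "D5Utr4e":  {"FIS": -0.135, "FIT": -0.095, "FST": 0.035, "Nm": 6.893},
    "D5Utr4f":  {"FIS": -0.042, "FIT": 0.054,  "FST": 0.092, "Nm": 2.467},
    "D7Utr4a":  {"FIS": 0.048,  "FIT": 0.299,  "FST": 0.264, "Nm": 0.697},
    "D7Utr4b":  {"FIS": -0.176, "FIT": -0.173, "FST": 0.002, "Nm": None},
    "D19Utr4a": {"FIS": -0.191, "FIT": -0.026, "FST": 0.138, "Nm": 1.562},
    "D19Utr4b": {"FIS": 0.383,  "FIT": 0.635,  "FST": 0.408, "Nm": 0.363},
}

#: Reported "Mean +/- SE" row of the F-statistics table.
FSTATS_REPORTED_SUMMARY = {
    "FIS_mean": -0.044, "FIS_se": 0.086,
    "FIT_mean": 0.156,  "FIT_se": 0.083,
    "FST_mean": 0.220,  "FST_se": 0.051,
    "Nm_mean": 1.872,   "Nm_se": 0.574,
}

#: Per-breed, per-locus neutrality deviates D; None = dash (undefined cell).
NEUTRALITY_D: dict[str, dict[str, float | None]] = {
    "BB":  dict(zip(LOCI, (0.842, 1.770, 0.059, 0.970, 0.794, -0.847, 0.755,
                           -1.006, 2.413, 0.896, -0.144, 0.807, 0.912, -0.301))),
    "WB":  dict(zip(LOCI, (-0.333, -0.333, -0.636, -1.636, -1.333, -1.000, -1.333,
                           -1.333, -0.636, -2.181, -0.333, -1.449, -1.333, 0.667))),
    "RB":  dict(zip(LOCI, (-1.000, -1.000, 1.080, -0.448, -1.333, -1.000, -1.636,
                           -1.333, -0.636, None, 0.667, -0.190, -1.333, 0.000))),
    "JAB": dict(zip(LOCI, (-0.453, 0.119, -0.791, -0.227, -1.386, None, -1.333,
                           None, None, None, -1.152, 1.054, 0.571, None))),
    "NZW": dict(zip(LOCI, (1.894, 0.494, 0.273, 1.207, 0.767, -0.229, -0.099,
                           -0.606, 2.545, 2.335, 0.351, 0.028, 1.912, -0.053))),
    "AR":  dict(zip(LOCI, (0.364, 0.000, -1.636, -1.636, -1.333, -1.000, -1.333,
                           -1.333, -1.333, -2.944, -1.333, -2.190, 0.667, -1.000))),
    "CH":  dict(zip(LOCI, (0.000, 0.667, -1.636, -1.636, -1.333, -1.000, -0.636,
                           -1.333, -0.636, 1.551, -0.333, 0.810, -1.333, -1.000))),
}

#: Reported breed means of D. Only WB, RB and JAB are arithmetically
#: consistent with the per-locus values above; the other four columns were
#: averaged by an unstated rule and are kept for reference only.
NEUTRALITY_REPORTED_MEANS = {
    "BB": 0.709, "WB": -0.943, "RB": -0.628, "JAB": -0.400,
    "NZW": 0.844, "AR": -1.074, "CH": -0.489,
}

#: Breed columns whose reported mean equals the arithmetic mean of the
#: defined per-locus values (at 3 decimals).
CONSISTENT_MEAN_BREEDS: tuple[str, ...] = ("WB", "RB", "JAB")
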