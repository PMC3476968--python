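"""Published per-subject benchmark statistics for the two EMG estimators.

These are the printed per-subject values from the clinical validation of
the methods (12 subjects: 7 normal sleepers, 2 obstructive sleep apnea,
3 periodic limb movement disorder).  They serve as *inputs* to the
aggregation/metrics operations: the raw recordings are not publicly
deposited, so acceptance of the summary arithmetic rests on reproducing
the printed derived values from the printed per-subject ones.
"""

# subject, group, method, sens, spec, ppv, npv, accuracy, kappa, f_measure
EPOCH_STATS = [
    (1, "N", "TDA", 0.99, 0.69, 0.56, 1.00, 0.78, 0.64, 0.72),
    (1, "N", "FDA", 1.00, 0.71, 0.60, 1.00, 0.80, 0.69, 0.75),
    (2, "N", "TDA", 0.99, 0.74, 0.65, 0.99, 0.82, 0.64, 0.79),
    (2, "N", "FDA", 0.99, 0.73, 0.63, 0.99, 0.81, 0.67, 0.77),
    (3, "N", "TDA", 1.00, 0.70, 0.58, 1.00, 0.79, 0.70, 0.73),
    (3, "N", "FDA", 0.99, 0.71, 0.59, 1.00, 0.79, 0.67, 0.74),
    (4, "N", "TDA", 0.98, 0.75, 0.68, 0.98, 0.83, 0.61, 0.80),
    (4, "N", "FDA", 0.98, 0.71, 0.60, 0.99, 0.79, 0.59, 0.74),
    (5, "N", "TDA", 0.99, 0.69, 0.56, 0.99, 0.77, 0.61, 0.71),
    (5, "N", "FDA", 0.99, 0.80, 0.73, 0.99, 0.82, 0.72, 0.99),
    (6, "N", "TDA", 0.99, 0.78, 0.71, 0.99, 0.85, 0.73, 0.83),
    (6, "N", "FDA", 0.99, 0.77, 0.71, 0.99, 0.85, 0.67, 0.82),
    (7, "N", "TDA", 0.99, 0.65, 0.47, 1.00, 0.73, 0.55, 0.63),
    (7, "N", "FDA", 1.00, 0.70, 0.57, 1.00, 0.78, 0.66, 0.73),
    (8, "O", "TDA", 0.99, 0.71, 0.59, 0.99, 0.79, 0.64, 0.74),
    (8, "O", "FDA", 0.99, 0.77, 0.71, 0.99, 0.85, 0.68, 0.82),
    (9, "O", "TDA", 1.00, 0.68, 0.53, 1.00, 0.76, 0.64, 0.69),
    (9, "O", "FDA", 0.99, 0.75, 0.67, 1.00, 0.83, 0.66, 0.80),
    (10, "P", "TDA", 0.95, 0.63, 0.44, 0.98, 0.71, 0.47, 0.60),
    (10, "P", "FDA", 0.94, 0.70, 0.58, 0.96, 0.77, 0.40, 0.72),
    (11, "P", "TDA", 0.99, 0.59, 0.31, 1.00, 0.66, 0.44, 0.48),
    (11, "P", "FDA", 0.99, 0.67, 0.52, 0.99, 0.76, 0.56, 0.68),
    (12, "P", "TDA", 0.96, 0.55, 0.19, 0.99, 0.59, 0.26, 0.32),
    (12, "P", "FDA", 0.98, 0.60, 0.34, 0.99, 0.67, 0.41, 0.51),
]

#: (subject, method) whose printed F-measure fits no candidate formula
#: (probable misprint in the published table); excluded from checks.
F_MEASURE_MISPRINTS = {(5, "FDA")}

# printed summary rows: group -> method -> (means, sds) per statistic
SUMMARY_ROWS = {
    ("N", "TDA"): ((0.99, 0.71, 0.60, 0.99, 0.80, 0.64, 0.74),
                   (0.01, 0.04, 0.08, 0.01, 0.04, 0.06, 0.07)),
    ("N", "FDA"): ((0.99, 0.73, 0.63, 0.99, 0.81, 0.67, 0.79),
                   (0.01, 0.04, 0.06, 0.01, 0.02, 0.04, 0.09)),
    ("NO", "TDA"): ((0.99, 0.71, 0.59, 0.99, 0.79, 0.64, 0.74),
                    (0.01, 0.04, 0.08, 0.01, 0.04, 0.05, 0.06)),
    ("NO", "FDA"): ((0.99, 0.74, 0.65, 0.99, 0.81, 0.67, 0.80),
                    (0.01, 0.04, 0.06, 0.01, 0.03, 0.03, 0.08)),
    ("NOP", "TDA"): ((0.99, 0.68, 0.52, 0.99, 0.76, 0.58, 0.67),
                     (0.02, 0.07, 0.15, 0.01, 0.07, 0.13, 0.15)),
    ("NOP", "FDA"): ((0.99, 0.72, 0.60, 0.99, 0.79, 0.62, 0.76),
                     (0.02, 0.05, 0.11, 0.01, 0.05, 0.11, 0.11)),
}

GROUPS = {"N": {"N"}, "NO": {"N", "O"}, "NOP": {"N", "O", "P"}}

# subject, psg_se, estimated_se, abs_diff, rel_diff (frequency-domain method)
SLEEP_EFFICIENCY = [
    (1, 98.2, 97.5, 0.7, 0.7),
    (2, 97.3, 96.9, 0.4, 0.4),
    (3, 97.8, 97.0, 0.9, 0.9),
    (4, 96.3, 96.3, 0.0, 0.0),
    (5, 97.2, 98.4, 1.2, 1.3),
    (6, 97.4, 97.6, 0.2, 0.2),
    (7, 98.9, 98.5, 0.4, 0.4),
    (8, 98.1, 98.2, 0.1, 0.1),
    (9, 98.8, 97.8, 0.9, 1.0),
    (10, 94.1, 96.6, 2.5, 2.7),
    (11, 97.9, 97.5, 0.5, 0.5),
    (12, 98.2, 97.0, 1.2, 1.2),
]
SLEEP_EFFICIENCY_SUMMARY = (97.5, 1.3, 97.4, 0.7, 0.8, 0.7, 0.8, 0.7)

# posture strata (time-domain method): posture -> (epoch counts, kappas)
# zero-epoch strata carry no kappa
POSTURE_EPOCHS = {
    "SUPINE": [627, 756, 681, 756, 687, 959, 849, 592, 863, 641, 565, 900],
    "LEFT": [173, 0, 137, 0, 277, 0, 0, 0, 0, 155, 336, 79],
    "RIGHT": [177, 81, 122, 81, 0, 44, 0, 383, 110, 151, 0, 0],
    "PRONE": [0] * 12,
}
POSTURE_KAPPAS = {
    "SUPINE": [0.68, 0.63, 0.72, 0.60, 0.56, 0.71, 0.55, 0.63, 0.66, 0.42, 0.56, 0.25],
    "LEFT": [0.60, 0.69, 0.70, 0.51, 0.38, 0.46],
    "RIGHT": [0.52, 0.65, 0.61, 0.65, 0.76, 0.64, 0.61, 0.46],
    "PRONE": [],
}
POSTURE_SUMMARY = {
    "SUPINE": (739.6, 128.8, 0.58, 0.13),
    "LEFT": (96.4, 119.5, 0.56, 0.13),
    "RIGHT": (95.8, 109.9, 0.61, 0.09),
}
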