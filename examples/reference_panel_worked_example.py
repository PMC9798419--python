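"""Worked example: re-run panel selection on the packaged reference table.

The table transcribes the seven stable blood miRNAs with their healthy
threshold windows (median ± 3·MAD of the time-course log2 fold changes)
and their observed log2FC in eleven cancer case/control datasets.  No
adjusted p-values are printed alongside, so the significance gate is
skipped and the denominator is all eleven datasets.
"""

import mirstab as ms

table = ms.load_reference_panel_table()
fc = table.drop(columns=["lower", "upper"])

report = ms.select_panel_from_windows(
    table[["lower", "upper"]], fc, min_outlier_fraction=0.8
)

print(report[["lower", "upper", "n_outlier", "outlier_fraction",
              "rank_score", "selected"]].round(3).to_string())
print()
implied_mad = ((table["upper"] - table["lower"]) / 6).round(3)
print("implied MAD per miRNA (window half-width / 3):")
print(implied_mad.to_string())
print()
print(f"{int(report['selected'].sum())}/7 miRNAs escape their healthy window "
      "in more than 80% of the 11 cancer datasets; every implied MAD is "
      "below the 0.2 stability cutoff. rank_score is the mean distance of "
      "the cancer fold changes from the window borders (log2 units).")
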