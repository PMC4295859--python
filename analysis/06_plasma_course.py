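"""Longitudinal plasma-biomarker statistics.

Generates the 41-patient panel (GDF-15, vWF, hsCRP over the BEP schedule)
and runs the full clinical battery: median (range) per timepoint with the
paired signed-rank change versus baseline, the prognosis-group comparison
at baseline, and the per-timepoint Spearman tracks between GDF-15 and the
endothelial/inflammation markers.
"""

from pathlib import Path

from dosetrend import (
    PlasmaDesign,
    correlation_track,
    generate_plasma_panel,
    group_compare,
    summarize_timecourse,
)

SEED = 20150115
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    panel, _ = generate_plasma_panel(PlasmaDesign(seed=SEED))

    for marker in panel.markers:
        summary = summarize_timecourse(panel, marker)
        safe = marker.replace("/", "_")
        summary.to_csv(RESULTS / f"plasma_course_{safe}.tsv", sep="\t", index=False)
        base = summary.iloc[0]["median"]
        peak = summary.loc[summary["median"].idxmax()]
        print(f"{marker}: baseline median {base:.1f}, peak {peak['median']:.1f} "
              f"at {peak['timepoint']} (p vs baseline = {peak['p_vs_baseline']:.2e})")

    u, p, summaries = group_compare(panel, "GDF-15", "c1d1", "igcccg_group")
    print("baseline GDF-15 by prognosis group:")
    for group, text in summaries.items():
        print(f"  {group}: {text}")
    print(f"  Mann-Whitney U = {u:.1f}, two-sided p = {p:.3f}")

    for other in ("vWF", "hsCRP"):
        track = correlation_track(panel, "GDF-15", other)
        track.to_csv(RESULTS / f"correlation_GDF-15_{other}.tsv", sep="\t", index=False)
        strongest = track.loc[track["r_s"].abs().idxmax()]
        print(f"GDF-15 vs {other}: strongest correlation r_s = {strongest['r_s']:.2f} "
              f"at {strongest['timepoint']} (p = {strongest['p']:.3f})")


if __name__ == "__main__":
    main()
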