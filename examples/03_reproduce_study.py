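"""Recompute the published study's headline numbers from the packaged tables.

Loads the integrity-gated measurement and patient fixtures and prints the
matching-variant statistics (two-way absolute agreement, single measures,
phases pooled), plus any published value the recomputation contradicts.
"""

import esovol as ev

table, records = ev.load_study_fixture()
report = ev.headline_stats(table, records)

mv = report["mean_volume_ml"]
print(f"mean tumor volume : manual {mv['manual']['mean']:.0f} ml "
      f"(range {mv['manual']['min']:.0f}-{mv['manual']['max']:.0f}), "
      f"semiauto {mv['semiauto']['mean']:.0f} ml "
      f"(range {mv['semiauto']['min']:.0f}-{mv['semiauto']['max']:.0f})")
h = report["headline"]
print(f"interobserver ICC : semiauto {h['interobserver_icc_semiauto']:.2f} "
      f"vs manual {h['interobserver_icc_manual']:.2f} "
      f"(Fisher p = {report['fisher_semiauto_vs_manual']['p']:.4f})")
print(f"intraobserver ICC : manual {h['intraobserver_icc_manual']:.2f}, "
      f"semiauto {h['intraobserver_icc_semiauto']:.2f}")
ba = report["bland_altman"]
print(f"LoA width         : semiauto {ba['semiauto']['width']:.1f} ml, manual {ba['manual']['width']:.1f} ml")
apd = report["abs_pct_diff"]
print(f"abs. pct. diff    : semiauto {apd['semiauto']['mean']:.0f}%, manual {apd['manual']['mean']:.0f}%")
sub = report["subgroups"]
print(f"subgroup ICC      : AC manual {sub['AC']['manual']['icc']:.2f}, "
      f"SCC semiauto {sub['SCC']['semiauto']['icc']:.2f}")
for flag in report["flags"]:
    print(f"flag: {flag}")
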