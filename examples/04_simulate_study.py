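"""Simulate the full two-observer experiment on synthetic patients.

Runs 23 phantom patients through both protocols (manual tracing of every
slice vs sparse key slices + interpolation + HU window) with two simulated
observers and two contrast phases, then compares interobserver agreement
between methods — the study design, with known ground truth.
"""

import esovol as ev

table = ev.simulate_study(n_patients=23, seed=1)

print(f"{len(table.df)} measurements "
      f"({len(table.patients)} patients x 2 methods x 2 observers x 2 phases)")
for method in ("manual", "semiauto"):
    pairs = table.interobserver_pairs(method)
    r = ev.icc(pairs, form="twoway_agreement")
    apd, _ = ev.abs_pct_diff_from_mean(pairs)
    err = table.df.query("method == @method")
    bias = ((err.volume_ml - err.true_volume_ml) / err.true_volume_ml).mean()
    print(f"{method:8s}: interobserver ICC {r.value:.3f}, "
          f"abs. pct. diff {apd:.1f} %, mean bias vs truth {100 * bias:+.1f} %")
# Sparse, carefully traced key slices feed one shared interpolation, so the
# semiautomatic volumes carry fewer independent noisy decisions per tumor:
# higher ICC, smaller percentage difference — the direction seen clinically.
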