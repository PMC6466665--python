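"""Degradation detection: does completeness track simulated sequence loss?

Deletes 5%, 10% and 30% of a synthetic genome in random 5 kb windows and
re-assesses it. The completeness drop should track the deleted fraction:
markers sit uniformly in the genome, so deleting a fraction f of the
sequence knocks out about f of them.
"""

import mycocheck as mc

markerset = mc.make_marker_set(n_families=20, n_multicopy=0, n_hde=0, rng_seed=15)
assembly, _ = mc.make_genome(markerset, rng_seed=16, target_length=1_000_000, n_contigs=4)
baseline = mc.full_report(assembly, markerset).pct_complete
print(f"baseline completeness: {baseline:.1f}%")

for fraction in (0.05, 0.10, 0.30):
    truncated, log = mc.truncate_assembly(assembly, fraction, window=5000, rng_seed=17)
    pct = mc.full_report(truncated, markerset).pct_complete
    print(
        f"removed {fraction:4.0%} in {len(log):2d} windows -> "
        f"completeness {pct:5.1f}%  (drop {baseline - pct:4.1f} points)"
    )
print()
print("Each drop is close to the simulated loss fraction times 100, within")
print("binomial noise for 20 markers.")
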