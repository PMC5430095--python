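"""Call somatic SNVs/InDels on a simulated pileup.

Plants a 25% VAF substitution and a 15% VAF insertion in a 200-position
pileup at ~800x, runs the quality-swept binomial caller with the default
thresholds, and prints the resulting calls.
"""

from panelcall import SNVConfig, call_pileup
from panelcall.simulate import SimulationConfig, TruthVariant, simulate_pileup

sim = SimulationConfig(
    seed=1, n_positions=200, depth_mean=800,
    truth_variants=(TruthVariant("chr1", 50, "T", 0.25),
                    TruthVariant("chr1", 120, "+AG", 0.15)),
)
columns, reference, truth = simulate_pileup(sim)
calls, nocalls = call_pileup(columns, reference=reference, config=SNVConfig())

print(f"{len(columns)} columns piled up; {len(calls)} variant calls\n")
print("chrom      pos  ref alt    depth   %SR   score  Qt  filter")
for c in calls:
    status = "PASS" if c.is_pass else ",".join(sorted(c.filter_status))
    print(f"{c.chrom}  {c.pos + 1:7d}  {c.ref}   {c.alt:5s} {c.depth:6d} "
          f"{c.sr_percent:5.1f} {c.score:7.1f}  {c.qt_called}  {status}")

# The score is -10*log10 of the binomial tail probability that sequencing
# error alone produced this many variant reads; anything > 50 is reported.
# Both planted variants come back at their simulated %SR; the hundreds of
# error-only columns yield no call.
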