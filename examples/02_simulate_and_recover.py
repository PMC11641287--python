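"""Generate a synthetic cohort bundle with planted axes and recover them.

The default configuration mirrors the study design the pipeline targets:
5 tumor / 5 normal paired circRNA arrays, 10 tumor/normal miRNA pairs, a
114-normal / 1097-tumor reference cohort, a 200-subject survival cohort,
and five planted axes (2 tumor-suppressor + 3 onco) at 1.5 log2 units.
"""

from circaxis import SyntheticConfig, generate, recovery_metrics, run_bundle

bundle = generate(SyntheticConfig(seed=1))
print("planted truth:")
for ax in bundle.truth:
    print(f"  {ax.gene_id} / {ax.circ_id} / {ax.mirna_id}  "
          f"{ax.axis_class}  delta={ax.delta}")

result = run_bundle(bundle)
print("\ncandidates surviving each cumulative evidence gate:")
for gate, n in result.filter_chain.items():
    print(f"  {gate:<20} {n}")

sens, fdp = recovery_metrics(result.panel, bundle.truth)
print(f"\nrecovered axes: {result.panel.horizontal_confidence}")
print(f"sensitivity = {sens:.2f}  (planted axes recovered)")
print(f"false-discovery proportion = {fdp:.2f}  (spurious / reported)")
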