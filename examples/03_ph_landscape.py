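"""Distance-stratified granule pH landscape of a healthy cell.

Generates cells whose peripheral granules span a broad pH range and whose
interior granules lean acidic, runs the full analysis chain, and bins the
recovered granule pH by normalized membrane distance (0 = plasma membrane,
1 = deepest interior point).

Printed per bin: granule count, mean pH, and the central-50% interval.
Peripheral bins should show a broad interval near [4.8, 5.8] and interior
bins a narrower acidic one near [4.2, 5.0]; the pooled mean lands near
pH 5.0.
"""

from phasorph.pipeline import run_landscape
from phasorph.profiles import ph_landscape

land = run_landscape(seed=1, n_scenes=4)

print(f"pooled granules: {len(land.records)}  mean pH {land.mean_ph:.2f}\n")
print("distance bin     n    mean pH   central 50%")
for p in ph_landscape(land.records, [0.0, 0.05, 0.15, 0.5, 1.0]):
    lo, hi = p.distance_bin
    if p.values.size:
        print(f"[{lo:.2f}, {hi:.2f})  {p.values.size:4d}    {p.mean_value:5.2f}"
              f"     [{p.central50[0]:.2f}, {p.central50[1]:.2f}]")
    else:
        print(f"[{lo:.2f}, {hi:.2f})     0        -")
print("\nGranules near the membrane are more diverse and less acidic on")
print("average than the deep-interior pool, which concentrates below pH 5.")
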