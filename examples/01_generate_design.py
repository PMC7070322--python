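"""Generate the response-surface design for the celecoxib impurity method.

A face-centred central composite design (CCF) over the three critical
method parameters: 8 factorial corners, 6 axial face points, and 3 centre
replicates for pure-error estimation — 17 runs covering each factor at
three levels.
"""

from aqbd import generate_ccf
from aqbd.datasets import celecoxib_factors

design = generate_ccf(celecoxib_factors(), n_center=3)
print(design.to_frame().to_string(index=False))
print(f"\n{design.n_runs} runs "
      f"({design.n_runs - design.n_center} distinct conditions + "
      f"{design.n_center} centre replicates).")
print("Each row is one HPLC run: acetonitrile % (v/v), flow rate (mL/min),")
print("column temperature (degC); the lab fills in the measured responses.")
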