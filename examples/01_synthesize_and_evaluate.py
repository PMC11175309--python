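"""Generate a synthetic multi-modal pair and score a naive fusion.

Builds one phantom pair (modality A: smooth tissue contrast; modality B:
edge-rich rendering of the same anatomy), fuses them by simple averaging,
and prints the eight-metric quality report.  The report shows what each
metric rewards: averaging keeps both sources represented (moderate SSIM
and SCD) but halves edge contrast, so QAB/F stays mid-range and rSFe is
clearly negative (missing spatial frequency relative to the sources).
"""

import numpy as np

from cirf import evaluate_all, synth_pair

pair = synth_pair(seed=0, size=128)
fused = np.clip(0.5 * (pair.a + pair.b), 0, 1)

report = evaluate_all(pair.a, pair.b, fused)
print("naive average fusion of phantom pair (seed 0, 128x128)")
for name, value in report.as_dict().items():
    print(f"  {name:9s} {value: .4f}")
print("\nrSFe < 0: averaging loses high-frequency detail; "
      "SSIM ~0.8: overall structure of both sources is retained.")
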