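"""Score generated sequences against a real pool with PRD, RMSE and FD.

PRD is the error energy relative to signal energy (in percent), RMSE the
pointwise root mean square error, and FD the discrete Frechet distance
between the two sequences as ordered (time, amplitude) curves.  All three
are computed after min-max normalization to [0, 1], and each generated
sequence is matched to the real window it reconstructs best.
"""

import numpy as np

from ecggan import SynthConfig, evaluate_generated, generate_dataset

real = [w.values for w in generate_dataset(
    SynthConfig(duration=5.0, seed=0), n_records=2, window_length=400
)]
rng = np.random.default_rng(1)

# a "good" generator: real signal plus small noise; a "bad" one: white noise
good = [r + rng.normal(0, 0.05, size=r.shape) for r in real[:4]]
bad = [rng.normal(0, 0.3, size=400) for _ in range(4)]

for label, generated in (("near-copy", good), ("white noise", bad)):
    report = evaluate_generated(real, generated, pairing="best")
    print(f"{label:12s} PRD={report.prd:8.3f} RMSE={report.rmse:.3f} "
          f"FD={report.fd:.3f}  ({report.n_pairs} pairs, {report.pairing} pairing)")
print("lower is better on all three; identical sequences would score 0/0/0")
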