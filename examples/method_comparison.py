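"""Compare held-out trajectory error of the collaborative model against the
multi-stage and one-stage controls over a few seeded replicates.

Run from the repository root (takes a couple of minutes):

    python examples/method_comparison.py
"""

import numpy as np

from mscolor.evaluation import rmse_ordering_replicate
from mscolor.synthetic import SimConfig

cfg = SimConfig(n_per_stage=[120, 120, 120], d=60, c=4, n_causal=8,
                n_gwas=8000, n_ref=1000)

rows = []
for seed in range(5):
    r = rmse_ordering_replicate(seed, cfg=cfg)
    rows.append(r)
    print(f"seed {seed}: mscolor {r['mscolor']:.4f}  msmml {r['msmml']:.4f}  "
          f"smml {r['smml']:.4f}  "
          f"ordered={r['mscolor'] <= r['msmml'] <= r['smml']}")

frac = np.mean([r["mscolor"] <= r["msmml"] <= r["smml"] for r in rows])
print(f"\nmscolor <= msmml <= smml in {frac:.0%} of replicates")
print("mean test RMSE:",
      {m: round(float(np.mean([r[m] for r in rows])), 4)
       for m in ("mscolor", "msmml", "smml")})
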