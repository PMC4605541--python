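"""Optional long-running benchmark: N = 1000 network, 5.5-hour experiment.

Replicates the large-network protocol (1000 observed neurons, double serial
scanning, sparsity-matched L1 MAP) at observation probabilities 1.0, 0.2 and
0.1.  Takes on the order of an hour on one CPU; not part of the test suite.

Usage: python scripts/large_network.py [--seed 0] [--hours 5.5] [--out results/large_network.json]
"""

import argparse
import json
import time
from pathlib import Path

import numpy as np

import shotgun_conn as sc
from shotgun_conn.ell import offdiag_nonzero_fraction, select_lambda


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--hours", type=float, default=5.5)
    ap.add_argument("--n", type=int, default=1000)
    ap.add_argument("--out", default="results/large_network.json")
    args = ap.parse_args()

    T = sc.hours_to_bins(args.hours)
    cfg = sc.NetworkGenConfig(N=args.n, p_conn=0.1, seed=args.seed)
    params = sc.generate_network(cfg)
    t0 = time.perf_counter()
    spikes = sc.simulate_glm(params, T, seed=args.seed + 1)
    print(f"simulated {args.n} x {T} bins in {time.perf_counter() - t0:.0f}s, "
          f"rate {spikes.S.mean() / sc.BIN_WIDTH_S:.2f} Hz")

    target = offdiag_nonzero_fraction(params.W)
    results = {}
    for p_obs in (1.0, 0.2, 0.1):
        scheme = sc.SchemeConfig(scheme="double_serial", seed=args.seed + 2)
        mask = sc.make_mask(scheme, args.n, T, p_obs)
        t0 = time.perf_counter()
        mom = sc.estimate_moments(spikes, mask)
        lam, res = select_lambda(mom, T, target)
        rep = sc.quality_metrics(params.W, res.W_hat)
        print(f"p_obs={p_obs}: C={rep.C:.3f} S={rep.S:.3f} Z={rep.Z:.3f} "
              f"({time.perf_counter() - t0:.0f}s)")
        results[str(p_obs)] = rep.as_dict()

    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(results, indent=2))


if __name__ == "__main__":
    main()
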