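#!/usr/bin/env python
"""Group-level spectrogram contrast and cluster permutation statistics.

Per participant the average high-intensity-odor spectrogram of the
source-reconstructed modality is contrasted with the clean-air average
(log-ratio baselined Morlet power, 4-100 Hz, -0.2..1 s). Across the
cohort a dependent-samples t map is evaluated with a 100-permutation
cluster test (participant-level sign flipping, 4-connectivity, mass
statistic). If a decoding table from 02 is present, the cohort is also
split into best/worst performers and each subgroup tested separately.

Reads results/cohort.h5 (+ optional results/linear_decoding.csv);
writes results/group_clusters.csv
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from odorbci.groupstats import (ClusterParams, cluster_perm_test,
                                split_performers)
from odorbci.pipeline import RunConfig, participant_contrast, preprocess_session
from odorbci.store import list_participants, read_store
from odorbci.synth import select_trials

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--store", type=Path, default=Path("results/cohort.h5"))
ap.add_argument("--decoding", type=Path,
                default=Path("results/linear_decoding.csv"))
ap.add_argument("--n-permutations", type=int, default=100)
ap.add_argument("--out", type=Path, default=Path("results/group_clusters.csv"))
args = ap.parse_args()

run = RunConfig(seed=args.seed, freq_step=4.0)
pids = list_participants(args.store)
diffs, freqs, times = [], None, None
for pid in pids:
    session = preprocess_session(
        select_trials(read_store(args.store, pid), {"high", "air"}), run)
    d, freqs, times = participant_contrast(session, run)
    diffs.append(d)
diffs = np.stack(diffs)


def report(name, sel):
    res = cluster_perm_test(diffs[sel],
                            ClusterParams(n_permutations=args.n_permutations,
                                          seed=args.seed),
                            freqs=freqs, times=times)
    rows = []
    for i, c in enumerate(res.clusters):
        fsel, tsel = c.mask.any(axis=1), c.mask.any(axis=0)
        rows.append(dict(group=name, cluster=i, sign=c.sign,
                         mass=round(c.mass, 2), p=c.p,
                         f_lo=res.freqs[fsel].min(), f_hi=res.freqs[fsel].max(),
                         t_lo=round(res.times[tsel].min(), 3),
                         t_hi=round(res.times[tsel].max(), 3)))
    n_sig = len(res.significant())
    print(f"{name}: {len(res.clusters)} cluster(s), {n_sig} significant "
          f"(p <= 0.05)")
    return rows


all_rows = report("all", np.arange(len(pids)))

if args.decoding.exists() and len(pids) >= 4:
    per = (pd.read_csv(args.decoding)
           .groupby("participant")["auc"].mean().to_dict())
    per = {p: per.get(p, 0.5) for p in pids}
    k = len(pids) // 2
    top, bottom = split_performers(per, k=k)
    idx = {p: i for i, p in enumerate(pids)}
    all_rows += report(f"top-{k}", np.array([idx[p] for p in top]))
    all_rows += report(f"bottom-{k}", np.array([idx[p] for p in bottom]))

args.out.parent.mkdir(parents=True, exist_ok=True)
pd.DataFrame(all_rows).to_csv(args.out, index=False)
print(f"cluster table written to {args.out}")
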