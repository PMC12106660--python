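#!/usr/bin/env python
"""End-to-end decoding with the 1-D residual network.

Raw conditioned epochs (120 Hz low-pass, 256 Hz, baseline-subtracted,
95th-percentile normalized, cropped to the first post-onset second) are
decoded by the convolutional ResNet under nested cross-validation with
validation-weighted inner ensembles. Desk-scale defaults (narrow net,
reduced inner fold count) keep a participant's run in minutes on one CPU.

Reads results/cohort.h5 (from 01); writes results/resnet_decoding.csv
"""

import argparse
from pathlib import Path

import pandas as pd

from odorbci.pipeline import RunConfig, decode_participant_net, preprocess_session
from odorbci.store import list_participants, read_store
from odorbci.synth import select_trials

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--store", type=Path, default=Path("results/cohort.h5"))
ap.add_argument("--modality", default="scalp_ebg",
                choices=["eeg", "scalp_ebg", "source_ebg", "sniff"])
ap.add_argument("--participants", type=int, default=1,
                help="how many participants to decode (training is the slow part)")
ap.add_argument("--k-outer", type=int, default=5)
ap.add_argument("--epochs", type=int, default=20)
ap.add_argument("--out", type=Path, default=Path("results/resnet_decoding.csv"))
args = ap.parse_args()

rows = []
for pid in list_participants(args.store)[:args.participants]:
    session = select_trials(read_store(args.store, pid), {"high", "air"})
    run = RunConfig(seed=args.seed, modality=args.modality,
                    k_outer=args.k_outer)
    proc = preprocess_session(session, run)
    res = decode_participant_net(proc, run, max_epochs=args.epochs)
    for fold, auc in enumerate(res.fold_aucs):
        rows.append(dict(participant=pid, modality=args.modality,
                         model="resnet1d", fold=fold, auc=auc))
    print(f"{pid} {args.modality}: mean test AUC {res.mean_auc:.3f} "
          f"over {args.k_outer} outer folds")

args.out.parent.mkdir(parents=True, exist_ok=True)
pd.DataFrame(rows).to_csv(args.out, index=False)
print(f"table written to {args.out}")
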