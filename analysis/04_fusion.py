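#!/usr/bin/env python
"""Multimodal fusion of scalp-EBG and the sniff trace.

Three combination schemes on one participant:
  late-linear — validation-AUC-weighted average of the two linear
      decoders' predicted probabilities;
  early       — channel concatenation (both modalities at 256 Hz) fed to
      one convolutional decoder;
  late-hybrid — dual-encoder network, embeddings concatenated into a
      single linear sigmoid head, trained jointly.

Reads results/cohort.h5 (from 01); writes results/fusion.csv
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from odorbci import features
from odorbci.evaluate import auc_roc, make_fold_plan
from odorbci.fusion import (FusionWeights, build_hybrid_net, early_fuse,
                            late_fuse_probabilities)
from odorbci.linear import L1LogRegFactory
from odorbci.net import NetDecoder, NetSpec, TrainSpec
from odorbci.pipeline import RunConfig, preprocess_session
from odorbci.preprocess import crop, percentile_normalize, resample
from odorbci.store import list_participants, read_store
from odorbci.synth import select_trials

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--store", type=Path, default=Path("results/cohort.h5"))
ap.add_argument("--epochs", type=int, default=15)
ap.add_argument("--out", type=Path, default=Path("results/fusion.csv"))
args = ap.parse_args()

pid = list_participants(args.store)[0]
run = RunConfig(seed=args.seed)
session = preprocess_session(
    select_trials(read_store(args.store, pid), {"high", "air"}), run)
ebg = session["scalp_ebg"]
sniff = session["sniff"]
y = ebg.labels
plan = make_fold_plan(y, k_outer=5, k_inner=5, seed=args.seed)
(otr, ote) = plan.outer[0]
(itr, iva) = plan.inner[0][0]

rows = []

# --- late fusion of linear decoders
params = features.TFRParams(freqs=np.arange(5.0, 101.0, 3.0))
X_ebg = features.linear_feature_matrix(ebg, params)
X_sniff = features.sniff_feature_matrix(sniff)
factory_e = L1LogRegFactory()
factory_s = L1LogRegFactory(pca_var=0.95)
m_e = factory_e.make(C=1.0).fit(X_ebg[itr], y[itr])
m_s = factory_s.make(C=1.0).fit(X_sniff[itr], y[itr])
w = FusionWeights.from_validation_aucs(
    auc_roc(m_e.predict_proba(X_ebg[iva])[:, 1], y[iva]),
    auc_roc(m_s.predict_proba(X_sniff[iva])[:, 1], y[iva]))
fused = late_fuse_probabilities(m_e.predict_proba(X_ebg[ote])[:, 1],
                                m_s.predict_proba(X_sniff[ote])[:, 1], w)
rows.append(dict(scheme="late-linear", auc=auc_roc(fused, y[ote]),
                 detail=f"w_ebg={w.w_a:.2f}"))

# --- raw epochs for the network schemes: both modalities at 256 Hz
# (sniff is 50 Hz low-passed at 200 Hz; harmonize rates for concatenation)
ebg_net = percentile_normalize(crop(ebg, (0.0, 1.0)))
sniff_matched = percentile_normalize(
    crop(resample(sniff, 256.0), (0.0, 1.0)))
fused_epochs = early_fuse(ebg_net, sniff_matched)
tspec = TrainSpec(learning_rate=1e-3, max_epochs=args.epochs, seed=args.seed)
dec = NetDecoder(NetSpec(fused_epochs.n_channels, fused_epochs.data.shape[-1],
                         base_filters=8, seed=args.seed), tspec)
dec.fit_with_val(fused_epochs.data[itr], y[itr],
                 fused_epochs.data[iva], y[iva])
rows.append(dict(scheme="early",
                 auc=auc_roc(dec.predict_proba(fused_epochs.data[ote])[:, 1],
                             y[ote]),
                 detail=f"{fused_epochs.n_channels}ch"))

# --- dual-encoder hybrid
net = build_hybrid_net(
    NetSpec(ebg_net.n_channels, ebg_net.data.shape[-1], base_filters=8,
            seed=args.seed),
    NetSpec(sniff_matched.n_channels, sniff_matched.data.shape[-1],
            base_filters=8, seed=args.seed + 1))
from odorbci.net import train_net

net, _ = train_net(net, ((ebg_net.data[itr], sniff_matched.data[itr]), y[itr]),
                   ((ebg_net.data[iva], sniff_matched.data[iva]), y[iva]),
                   tspec)
rows.append(dict(scheme="late-hybrid",
                 auc=auc_roc(net.forward((ebg_net.data[ote],
                                          sniff_matched.data[ote])), y[ote]),
                 detail=f"emb={net.embedding_dim}"))

df = pd.DataFrame(rows)
args.out.parent.mkdir(parents=True, exist_ok=True)
df.to_csv(args.out, index=False)
print(df.to_string(index=False))
print(f"table written to {args.out}")
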