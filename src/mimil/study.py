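"""Seed-averaged comparative evaluation of MI-MIL and its baselines.

One *run* of the study protocol: draw a person-disjoint split, train each
model kind on the training bags with early stopping on the validation bags,
and score the held-out test participants. Runs are repeated over the
configured training seeds and metrics averaged. To reduce the contingency of
a single 3+3-participant test draw, each training seed uses its own split
(derived deterministically from the base seed); all model kinds share every
split, so the comparison between models stays paired.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np

from .features import FeatureBag
from .model import (
    Metrics,
    ModelConfig,
    TrainedModel,
    bags_to_arrays,
    evaluate,
    flat_supervised_baseline,
    person_disjoint_split,
    split_bags,
    train_model,
)


def run_study(
    bags: Sequence[FeatureBag],
    cfg: Optional[ModelConfig] = None,
    base_seed: int = 0,
    kinds: Sequence[str] = ("mimil", "attention_mil", "flat"),
    per_seed_splits: bool = True,
) -> Dict[str, dict]:
    """Train and evaluate each model kind under the shared protocol.

    Returns, per kind, the seed-averaged metrics plus per-seed F1 scores and
    (for the MIL kinds) the trained models of each seed.
    """
    cfg = cfg or ModelConfig()
    participants = {b.participant_id: b.group for b in bags}
    out: Dict[str, dict] = {
        k: {"f1_per_seed": [], "metrics_per_seed": [], "models": []} for k in kinds
    }
    for i, seed in enumerate(cfg.seeds):
        split_seed = base_seed * 101 + seed if per_seed_splits else base_seed
        split = person_disjoint_split(participants, seed=split_seed)
        tr, va, te = split_bags(bags, split)
        txs, ty, _ = bags_to_arrays(tr)
        vxs, vy, _ = bags_to_arrays(va)
        exs, ey, _ = bags_to_arrays(te)
        for kind in kinds:
            if kind == "flat":
                metrics, clf = flat_supervised_baseline(tr, te, seed=seed, val_bags=va)
                model = clf
            else:
                model = train_model(
                    txs, ty, vxs, vy, cfg, seed=seed, kind=kind,
                    representation=bags[0].representation,
                )
                metrics = evaluate(model, exs, ey)
            out[kind]["f1_per_seed"].append(metrics.f1)
            out[kind]["metrics_per_seed"].append(metrics)
            out[kind]["models"].append(model)
            out[kind].setdefault("splits", []).append(split)
    for kind in kinds:
        vals = out[kind]["metrics_per_seed"]
        out[kind]["mean"] = Metrics(
            **{
                f: float(np.mean([getattr(m, f) for m in vals]))
                for f in ("accuracy", "f1", "precision", "recall", "specificity")
            }
        )
    return out
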