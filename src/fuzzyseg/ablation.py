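"""Fuzzy-block placement ablation grids.

Three experimental designs over where the spatial/channel fuzzy blocks sit:

* ``cumulative`` — blocks 1..k carry both fuzzy blocks, for k = 1..5;
* ``individual`` — only block k carries both fuzzy blocks, for k = 1..5;
* ``grid`` — all five blocks carry (neither / spatial only / channel only /
  both), the four-row on-off table.

Each run trains and evaluates a fresh network under the same ``RunConfig``
protocol and contributes one row (encoder, SFB, CFB, placement, tumor IoU,
mean IoU) to the result table.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .train import RunConfig, evaluate_model, train_network

logger = logging.getLogger(__name__)

__all__ = ["placement_specs", "run_ablation"]


def placement_specs(design: str) -> list[tuple[str, tuple[tuple[bool, bool], ...]]]:
    """Named placement vectors for one design (see module docstring)."""
    off = (False, False)
    on = (True, True)
    if design == "cumulative":
        return [(f"blocks_1-{k}", tuple(on if i < k else off for i in range(5)))
                for k in range(1, 6)]
    if design == "individual":
        return [(f"block_{k}", tuple(on if i == k - 1 else off for i in range(5)))
                for k in range(1, 6)]
    if design == "grid":
        return [(name, tuple((s, c) for _ in range(5)))
                for name, (s, c) in [("baseline", (False, False)), ("sfb", (True, False)),
                                     ("cfb", (False, True)), ("sfb+cfb", (True, True))]]
    raise ValueError(f"unknown ablation design {design!r}; "
                     "choose from cumulative, individual, grid")


def run_ablation(config: RunConfig, samples, designs=("cumulative", "individual", "grid"),
                 out_dir: str | Path | None = None, tumor_class: int = 4) -> pd.DataFrame:
    """Run every placement of the requested designs; returns one row per run."""
    rng = np.random.default_rng(config.seed)
    n = len(samples)
    order = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n)))
    n_test = max(1, int(round(0.2 * n)))
    test = [samples[i] for i in order[:n_test]]
    val = [samples[i] for i in order[n_test:n_test + n_val]]
    fit = [samples[i] for i in order[n_test + n_val:]]

    rows = []
    for design in designs:
        for name, placement in placement_specs(design):
            net_cfg = replace(config.network, fuzzy_placement=placement)
            run_cfg = replace(config, network=net_cfg)
            result = train_network(run_cfg, fit, val)
            report = evaluate_model(result.model, test)
            any_s = any(p[0] for p in placement)
            any_c = any(p[1] for p in placement)
            rows.append({
                "design": design,
                "placement": name,
                "encoder": config.network.encoder_family,
                "SFB": any_s,
                "CFB": any_c,
                "tumor_IoU": float(report.per_class_iou[tumor_class]),
                "mean_IoU": report.miou,
            })
            logger.info("ablation %s/%s: tumor IoU %.4f, mIoU %.4f",
                        design, name, rows[-1]["tumor_IoU"], rows[-1]["mean_IoU"])
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "ablation.csv", index=False)
    return table
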