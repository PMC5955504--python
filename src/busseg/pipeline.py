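"""End-to-end orchestration shared by the CLI and scripts.

Glues the stages together: phantom generation -> preprocessing -> grouped
ensemble training -> majority voting -> DRLS and original-U-net comparators ->
Dice/TPF/FPF tables, threshold and member-count sweeps, and the paired test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import metrics as M
from .drls import DRLSConfig, DRLSSegmenter
from .ensemble import (EnsembleConfig, MultiUNetEnsemble, member_count_sweep,
                       vote_threshold_sweep)
from .network import NetworkConfig, UNetSegmenter
from .preprocess import PreprocessConfig, resize_pad, standardize, unmap

log = logging.getLogger(__name__)

__all__ = ["prepare_arrays", "original_output_to_grid", "run_comparison"]


def prepare_arrays(dataset, input_size: int):
    """Resize-pad + standardize a dataset onto the network grid.

    Returns (X, y, groups, placements, images, masks): float32 images of shape
    (n, input_size, input_size), aligned binary masks, patient ids, and the
    placement records needed to map predictions back.
    """
    X, y, groups, placements = [], [], [], []
    for img, msk in dataset:
        raster, mask, placement = resize_pad(img, msk, int(input_size))
        X.append(standardize(raster).astype(np.float32))
        y.append(mask)
        groups.append(img.patient_id)
        placements.append(placement)
    return (np.stack(X), np.stack(y), groups, placements,
            [d[0] for d in dataset], [d[1] for d in dataset])


def original_output_to_grid(mask_out: np.ndarray, input_size: int,
                            placement) -> np.ndarray:
    """Embed a valid-convolution output into its input grid, then unmap.

    The unpadded comparator predicts only the central output_size region of
    its input; everything outside that field of view is background.
    """
    o = mask_out.shape[-1]
    margin = (input_size - o) // 2
    canvas = np.zeros((input_size, input_size), dtype=np.uint8)
    canvas[margin : margin + o, margin : margin + o] = mask_out
    return unmap(canvas, placement)


def _records(preds, truths, images, method: str, fpf_denominator="background"):
    out = []
    for i, (p, t, img) in enumerate(zip(preds, truths, images)):
        strata = {"class": img.meta.get("class", "unknown"), "method": method}
        out.append(M.evaluate_pair(p, t.pixels, image_id=f"im{i:03d}",
                                   strata=strata, fpf_denominator=fpf_denominator))
    return out


def run_comparison(
    train_dataset,
    test_dataset,
    mu_config: NetworkConfig | None = None,
    ou_config: NetworkConfig | None = None,
    drls_config: DRLSConfig | None = None,
    n_folds: int = 10,
    rng_seed: int = 0,
    include_original: bool = True,
    sweep_thresholds=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
) -> dict:
    """Train the voting ensemble and both comparators, evaluate on held-out data.

    Evaluation happens on the ensemble's preprocessed grid (the clinical
    protocol: all methods are scored on the same downsampled frame).  Returns
    a dict with per-method evaluation records, the summary table, sweep
    curves, and the paired ensemble-vs-original test.
    """
    mu_config = mu_config or NetworkConfig.scale_profile("multi_unet")
    drls_config = drls_config or DRLSConfig()

    Xtr, ytr, gtr, _, _, _ = prepare_arrays(train_dataset, mu_config.input_size)
    Xte, yte, gte, _, test_images, test_masks = prepare_arrays(
        test_dataset, mu_config.input_size)
    yte_masks = [m for m in yte]

    log.info("training %d-member ensemble on %d images", n_folds, len(Xtr))
    ensemble = MultiUNetEnsemble(net_config=mu_config, n_folds=n_folds,
                                 random_state=rng_seed)
    ensemble.fit(Xtr, ytr, groups=gtr)

    maps_per_image = ensemble.member_maps(Xte)
    mu_preds = ensemble.predict(Xte)
    # evaluation truths live on the ensemble grid; strata come from the images
    from .phantom import SegmentationMask
    truth_masks = [SegmentationMask(m) for m in yte_masks]
    results = {"multi_unet": _records(mu_preds, truth_masks, test_images,
                                      "multi_unet")}

    log.info("running DRLS comparator")
    drls = DRLSSegmenter(drls_config)
    drls_preds = [
        drls.segment(Xte[i], truth_masks[i]).pixels for i in range(len(Xte))
    ]
    results["drls"] = _records(drls_preds, truth_masks, test_images, "drls")

    single = None
    if include_original:
        log.info("training original-U-net comparator")
        ou_config = ou_config or NetworkConfig.scale_profile("original_unet")
        Xtr_o, ytr_o, gtr_o, _, _, _ = prepare_arrays(
            train_dataset, ou_config.input_size)
        Xte_o, _, _, pte_o, _, _ = prepare_arrays(test_dataset, ou_config.input_size)
        ou = UNetSegmenter(config=ou_config, random_state=rng_seed)
        ou.fit(Xtr_o, ytr_o, patient_ids=gtr_o)
        ou_out = ou.predict(Xte_o)
        # map the valid-convolution field of view back onto the ensemble grid
        eval_cfg = PreprocessConfig(target_size=mu_config.input_size)
        ou_preds = []
        for i in range(len(Xte_o)):
            full = original_output_to_grid(ou_out[i], ou_config.input_size, pte_o[i])
            regrid, _, _ = resize_pad(full.astype(float), None, eval_cfg)
            ou_preds.append((regrid > 0.5).astype(np.uint8))
        results["original_unet"] = _records(ou_preds, truth_masks, test_images,
                                            "original_unet")

    rows = []
    for method, recs in results.items():
        df = M.evaluate_set(recs)
        row = {"method": method}
        for metric in ("dice", "tpf", "fpf"):
            row[f"{metric}_mean"] = df.loc["all", f"{metric}_mean"]
            row[f"{metric}_std"] = df.loc["all", f"{metric}_std"]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("method")

    threshold_curve = vote_threshold_sweep(
        maps_per_image, yte_masks, sweep_thresholds,
        EnsembleConfig(n_members=n_folds))
    count_curve = member_count_sweep(
        maps_per_image, yte_masks, range(1, n_folds + 1),
        EnsembleConfig(n_members=n_folds))

    comparison = None
    if include_original:
        comparison = M.paired_comparison(results["multi_unet"],
                                         results["original_unet"])

    return {
        "ensemble": ensemble,
        "records": results,
        "table": table,
        "threshold_curve": threshold_curve,
        "member_count_curve": count_curve,
        "paired_test": comparison,
        "maps_per_image": maps_per_image,
        "test_truths": yte_masks,
    }
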