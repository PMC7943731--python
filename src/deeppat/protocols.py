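"""Canonical evaluation protocols at laptop scale.

These functions fix the study conditions used by the shipped benchmark and
the reproduction script: a 64 x 64 grid with 200 synthetic phantoms for
the main training run, a single-image memorization run, a two-seed
two-ratio network-family comparison at 32 x 32, and the TV-baseline ratio
sweep on a piecewise-constant nested-ellipse fixture.  All randomness is
derived from the ``seed`` argument.

Problem sizes here are deliberately small enough for a single CPU; they
trade absolute reconstruction quality for a protocol that anyone can rerun
end to end (see docs/methods.md for what these scales do and do not show).
"""

from __future__ import annotations

import numpy as np

from .phantom_forge import DatasetSplit, generate_phantom, split_dataset
from .quality_metrics import psnr, ssim
from .reconstructors import (NetworkSpec, TrainConfig, build_model, reconstruct,
                             train)
from .sensing import build_gaussian_matrix, measure
from .sparse_recovery import DEFAULT_TV_LAMBDA, TVProblem, tv_minimize

__all__ = ["nested_ellipse_phantom", "desk_unet_run", "single_image_overfit",
           "family_ordering_smoke", "tv_ratio_sweep"]


def nested_ellipse_phantom(n: int = 64) -> np.ndarray:
    """Piecewise-constant two-ellipse test image in [-1, 1] (TV-friendly)."""
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    img = np.full((n, n), -1.0)
    img[((yy - n / 2) / (0.41 * n)) ** 2 + ((xx - n / 2) / (0.31 * n)) ** 2 <= 1] = 0.2
    img[((yy - n / 2) / (0.19 * n)) ** 2 + ((xx - n / 2) / (0.125 * n)) ** 2 <= 1] = 0.8
    return img


def desk_unet_run(seed: int = 7, *, side: int = 64, num_phantoms: int = 200,
                  ratio: float = 0.3, epochs: int = 20) -> dict:
    """The main desk-scale run: U-Net at ratio 0.3 on 200 phantoms.

    Trains the depth-3 / base-8 U-Net with l1 loss, Adam, learning rate
    0.005, batch size 1 for 20 epochs and evaluates SSIM on the held-out
    test fifth against the raw K^T v proxy baseline.
    """
    phantoms = [generate_phantom(side, 3, seed + i) for i in range(num_phantoms)]
    split = split_dataset(phantoms, 0.8, seed)
    K = build_gaussian_matrix(side, ratio, seed)
    model = build_model(NetworkSpec("unet", depth=3, base_channels=8), K, seed)
    train(model, split, TrainConfig(epochs=epochs, seed=seed,
                                    undersampling_ratio=ratio))
    ss_net, ss_proxy, ps_net = [], [], []
    for ph in split.test:
        v = measure(K, ph)
        rec = reconstruct(model, v)
        ss_net.append(ssim(rec, ph))
        ps_net.append(psnr(rec, ph))
        ss_proxy.append(ssim(model.proxy_image(v), ph))
    return {
        "epoch1_loss": model.train_history[0][1],
        "final_loss": model.train_history[-1][1],
        "mean_test_ssim": float(np.mean(ss_net)),
        "mean_test_psnr": float(np.mean(ps_net)),
        "mean_proxy_ssim": float(np.mean(ss_proxy)),
        "n_test": len(split.test),
        "history": model.train_history,
    }


def single_image_overfit(seed: int = 7, *, side: int = 64, ratio: float = 0.3,
                         epochs: int = 800, family: str = "resunet") -> dict:
    """Memorization check: one phantom, one matrix, long training.

    A network that cannot drive its training loss to near zero on a single
    image has a defect; with the residual U-Net this run reaches SSIM
    above 0.99 against its target.
    """
    ph = generate_phantom(side, 3, seed + 35)
    K = build_gaussian_matrix(side, ratio, seed)
    split = DatasetSplit(train=[ph], test=[ph], train_fraction=0.5)
    model = build_model(NetworkSpec(family, depth=3, base_channels=8), K, seed)
    train(model, split, TrainConfig(epochs=epochs, seed=seed,
                                    undersampling_ratio=ratio))
    rec = reconstruct(model, measure(K, ph))
    return {
        "epoch1_loss": model.train_history[0][1],
        "final_loss": model.train_history[-1][1],
        "ssim": ssim(rec, ph),
        "psnr": psnr(rec, ph),
    }


def family_ordering_smoke(seed: int = 0, *, seeds=None, side: int = 32,
                          num_phantoms: int = 100, ratios=(0.5, 0.05),
                          epochs: int = 20) -> dict:
    """Two-seed, two-ratio comparison of proxy / cnn3 / unet / resunet.

    Returns per-(family, ratio, seed) mean test SSIM plus, per family, the
    grand mean over the ratio grid and its cross-seed standard deviation.
    Matched budgets: every family trains on the same split, matrix, epoch
    count and optimizer settings.
    """
    seeds = tuple(seeds) if seeds is not None else (seed, seed + 1)
    cells = {}
    for s in seeds:
        phantoms = [generate_phantom(side, 2, 1000 * s + i)
                    for i in range(num_phantoms)]
        split = split_dataset(phantoms, 0.8, s)
        for ratio in ratios:
            K = build_gaussian_matrix(side, ratio, s)
            ref = build_model(NetworkSpec("cnn3", base_channels=8), K, s)
            cells[("proxy-input", ratio, s)] = float(np.mean(
                [ssim(ref.proxy_image(measure(K, ph)), ph) for ph in split.test]))
            for family in ("cnn3", "unet", "resunet"):
                model = build_model(
                    NetworkSpec(family, depth=3, base_channels=8), K, s)
                train(model, split, TrainConfig(epochs=epochs, seed=s,
                                                undersampling_ratio=ratio))
                cells[(family, ratio, s)] = float(np.mean(
                    [ssim(reconstruct(model, measure(K, ph)), ph)
                     for ph in split.test]))
    summary = {}
    for family in ("proxy-input", "cnn3", "unet", "resunet"):
        per_seed = [float(np.mean([cells[(family, r, s)] for r in ratios]))
                    for s in seeds]
        summary[family] = {
            "mean_ssim": float(np.mean(per_seed)),
            "sd_across_seeds": float(np.std(per_seed, ddof=1))
            if len(per_seed) > 1 else 0.0,
            "per_ratio": {r: float(np.mean([cells[(family, r, s)]
                                            for s in seeds])) for r in ratios},
        }
    return {"cells": cells, "summary": summary, "seeds": seeds,
            "ratios": tuple(ratios)}


def tv_ratio_sweep(seed: int = 11, *, side: int = 64,
                   ratios=(0.05, 0.1, 0.3, 0.5), lam: float = DEFAULT_TV_LAMBDA,
                   max_iters: int = 200) -> dict:
    """TV-minimization PSNR/SSIM across the undersampling-ratio grid
    on the noiseless nested-ellipse fixture."""
    ph = nested_ellipse_phantom(side)
    out = {}
    for ratio in ratios:
        K = build_gaussian_matrix(side, ratio, seed)
        v = measure(K, ph)
        sol = tv_minimize(TVProblem(matrix=K, data=v, lambda_tv=lam,
                                    max_iters=max_iters))
        out[ratio] = {"psnr": psnr(sol.image.pixels, ph),
                      "ssim": ssim(sol.image.pixels, ph),
                      "converged": sol.converged,
                      "iterations": sol.iterations_run}
    return out
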