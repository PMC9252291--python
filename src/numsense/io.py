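"""Readers/writers for stimulus sets and experiment results.

Stimulus sets are written as one lossless PNG per image plus a compressed
array archive for the whole set, with a JSON sidecar recording set id, seed,
per-image numerosity and item bounding boxes.  Experiment results are written
as tidy CSV tables (per-unit curves, preference distributions, Gaussian-fit
tables, slope summaries) plus a JSON summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import tuning
from .stimuli import StimulusImage


def save_stimulus_set(images, outdir, set_id: int, seed=None) -> Path:
    """Write PNGs, an .npz stack and a JSON sidecar for one control set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack = np.stack([img.intensities for img in images])
    np.savez_compressed(outdir / f"set{set_id}_images.npz", images=stack)
    meta = {"set_id": set_id, "seed": seed, "images": []}
    for img in images:
        name = f"set{set_id}_n{img.numerosity:02d}.png"
        Image.fromarray((img.intensities * 255).astype(np.uint8), mode="L").save(
            outdir / name
        )
        meta["images"].append(
            {
                "file": name,
                "numerosity": img.numerosity,
                "item_bounding_boxes": [list(it.bounding_box) for it in img.items],
            }
        )
    sidecar = outdir / f"set{set_id}_meta.json"
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def load_stimulus_set(outdir, set_id: int) -> np.ndarray:
    """Load the image stack of one saved control set."""
    with np.load(Path(outdir) / f"set{set_id}_images.npz") as npz:
        return npz["images"]


def curves_frame(result) -> pd.DataFrame:
    """Per-unit mean tuning curves of an ExperimentResult, long format."""
    rows = []
    for sid, s in result.sets.items():
        for c in s.curves:
            for n, resp in zip(tuning.NUMEROSITIES, c.mean_response):
                rows.append(
                    {
                        "set_id": sid,
                        "unit_row": c.unit[0],
                        "unit_col": c.unit[-1],
                        "numerosity": int(n),
                        "mean_response": float(resp),
                        "preferred_numerosity": c.preferred_numerosity,
                    }
                )
    return pd.DataFrame(rows)


def distribution_frame(result) -> pd.DataFrame:
    rows = [
        {"set_id": sid, "numerosity": int(n), "proportion": float(p)}
        for sid, s in result.sets.items()
        for n, p in zip(tuning.NUMEROSITIES, s.distribution)
    ]
    return pd.DataFrame(rows)


def fits_frame(result, which: str = "unit") -> pd.DataFrame:
    """Gaussian-fit table: one row per (set, scale, fitted curve)."""
    rows = []
    for sid, s in result.sets.items():
        table = s.unit_fits if which == "unit" else s.pooled_fits
        for scale_id, fits in table.items():
            for f in fits:
                rows.append(
                    {
                        "set_id": sid,
                        "scale": scale_id,
                        "preferred_numerosity": f.preferred_numerosity,
                        "amplitude": f.amplitude,
                        "center": f.center,
                        "sigma": f.sigma,
                        "r_square": f.r_square,
                        "converged": f.converged,
                    }
                )
    return pd.DataFrame(rows)


def summary_dict(result) -> dict:
    out = {
        "condition": result.config.condition,
        "repeats": result.config.repeats,
        "seed": result.config.seed,
        "mean_r_square": {
            sc: result.mean_r2(sc) for sc in tuning.SCALE_ORDER
        },
        "sigma_slope": {
            sc: result.mean_slope(sc) for sc in tuning.SCALE_ORDER
        },
        "compressed_sigma_slope": result.compressed_slope(),
    }
    if result.sweep_distributions:
        out["sweep"] = {
            str(sigma): {str(sid): list(map(float, d))
                         for sid, d in per_set.items()}
            for sigma, per_set in result.sweep_distributions.items()
        }
    return out


def save_experiment(result, outdir) -> Path:
    """Write the CSV tables and JSON summary of one experiment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    curves_frame(result).to_csv(outdir / "unit_curves.csv", index=False)
    distribution_frame(result).to_csv(
        outdir / "preference_distribution.csv", index=False
    )
    fits_frame(result, "unit").to_csv(outdir / "unit_fits.csv", index=False)
    fits_frame(result, "pooled").to_csv(outdir / "pooled_fits.csv", index=False)
    path = outdir / "summary.json"
    path.write_text(json.dumps(summary_dict(result), indent=2, default=float))
    return path


def plot_experiment(result, outdir) -> list:
    """Figure panels per control set: pooled curves (linear and log2 axes),
    preference distribution, goodness of fit per scale, width vs preference."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sid, s in result.sets.items():
        fig, axes = plt.subplots(1, 5, figsize=(22, 3.6))
        for pc in s.pooled.values():
            if pc.absent:
                continue
            axes[0].plot(tuning.NUMEROSITIES, pc.response, lw=0.8)
            axes[1].plot(np.log2(tuning.NUMEROSITIES), pc.response, lw=0.8)
        axes[0].set(xlabel="numerosity", ylabel="normalized response",
                    title=f"set {sid}: pooled tuning (linear)")
        axes[1].set(xlabel="log2 numerosity", title="pooled tuning (log2)")
        axes[2].bar(tuning.NUMEROSITIES, s.distribution, color="gray")
        axes[2].set(xlabel="preferred numerosity", ylabel="proportion",
                    title="preference distribution")
        axes[3].bar(range(4), [s.r2_mean[sc] for sc in tuning.SCALE_ORDER],
                    tick_label=list(tuning.SCALE_ORDER), color="steelblue")
        axes[3].set(ylabel="mean r-square", title="goodness of fit by scale")
        for sc, marker in zip(tuning.SCALE_ORDER, "o^sd"):
            pts = [(f.preferred_numerosity, f.sigma)
                   for f in s.unit_fits[sc] if f.converged]
            if pts:
                x, y = np.array(pts).T
                axes[4].scatter(x, y, s=6, marker=marker, label=sc, alpha=0.4)
        axes[4].set(xlabel="preferred numerosity", ylabel="fit sigma",
                    title="tuning width vs preference")
        axes[4].legend(fontsize=7)
        fig.tight_layout()
        path = outdir / f"{result.config.condition}_set{sid}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
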