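"""Shared fixtures: small phantom builders and a naive brute-force oracle."""

from __future__ import annotations

import numpy as np
import pytest

import rgbelisa as rg
from rgbelisa.phantom import derived_rng


def small_spec(law="log", noise=2.0, seed=0, base_color=None, **overrides):
    """A reduced-size phantom (fast to render) with the default contrast,
    inlet larger than the default 200 px window."""
    kw = dict(
        image_height=420,
        image_width=560,
        inlet_origin=(80, 150),
        inlet_size=260,
        response_law=law,
        noise_sd=noise,
        seed=seed,
    )
    if base_color is not None:
        kw["base_color"] = tuple(base_color)
    kw.update(overrides)
    return rg.PhantomSpec(**kw)


def jittered_base(seed):
    """Per-seed base color: batch-to-batch illumination variation."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))
    return tuple(np.array([235.0, 228.0, 210.0]) + rng.uniform(-6, 6, 3))


def render_series(law, noise, seed, levels=rg.DEFAULT_LEVELS, replicates=1, **spec_overrides):
    """Render a phantom calibration series and extract its ROIs."""
    spec = small_spec(law=law, noise=noise, seed=seed,
                      base_color=jittered_base(seed), **spec_overrides)
    pairs = []
    for i, conc in enumerate(levels):
        for j in range(replicates):
            img = rg.render_phantom(spec, conc, rng=derived_rng(seed, i, j))
            roi = rg.extract_roi(img, window=spec_overrides.get("window", 200))
            pairs.append((float(conc), roi))
    return rg.ConcentrationSeries.from_rois(pairs)


def tiny_series(law, noise, seed, window=64):
    """A very small series (tiny images) for oracle-equivalence runs."""
    spec = small_spec(
        law=law, noise=noise, seed=seed, base_color=jittered_base(seed),
        image_height=180, image_width=240, inlet_origin=(40, 60), inlet_size=100,
    )
    pairs = []
    for i, conc in enumerate(rg.DEFAULT_LEVELS):
        img = rg.render_phantom(spec, conc, rng=derived_rng(seed, i, 0))
        roi = rg.extract_roi(img, window=window)
        pairs.append((float(conc), roi))
    return rg.ConcentrationSeries.from_rois(pairs)


def naive_grid_search(rois, concentrations, models, step, lo=-1.0, hi=1.0, tie_round=6):
    """Independent brute-force enumerator: nested loops over all weight
    triples, per-triple pixel scoring and model fitting, first strict
    improvement on the rounded R^2 wins (= lexicographically smallest tie).
    """
    ks = range(round(lo / step), round(hi / step) + 1)
    winners = {}
    for kind in models:
        best_key = None
        best = None
        for ka in ks:
            for kb in ks:
                for kg in ks:
                    if ka == 0 and kb == 0 and kg == 0:
                        continue
                    a, b, g = ka * step, kb * step, kg * step
                    scores = np.array(
                        [np.mean(a * r.R + b * r.G + g * r.B) for r in rois]
                    )
                    fit = rg.fit_model(kind, concentrations, scores)
                    key = round(fit.r_squared, tie_round)
                    if best_key is None or key > best_key:
                        best_key = key
                        best = ((a, b, g), fit)
        winners[kind] = best
    return winners
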