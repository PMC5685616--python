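"""Shared study configuration for the numbered analysis scripts.

The desk-scale study region: a 100 x 120 grid at 2.5 arc-minutes with six
continuous climate-like predictors plus an 11-class habitat mosaic, ten
species with 150 presence records each, reserves sited on richness
hotspots, three future time slices under a severe (A2a-like) and a
moderate (B2a-like) emissions scenario, and a background sample of 2000
cells for model fitting.
"""

from sdmshift.pipeline import RunConfig

SEED = 1


def study_config(seed: int = SEED) -> RunConfig:
    return RunConfig.from_dict(
        {
            "seed": seed,
            "simulate": {
                "pa_placement": "richness-biased",
                # bioclim-style redundancy among the temperature-like and
                # precipitation-like layers, for the VIF stage to resolve
                "collinear_pairs": [[0, 1, 0.97], [3, 4, 0.96]],
            },
            "model": {"background_n": 2000},
            "pa": {"n_random_pixels": 1000},
        }
    )
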