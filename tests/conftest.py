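"""Shared fixtures: one default synthetic dataset and pipeline run per
session, plus a factory for zero-effect (null) configurations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from strainatac import RunConfig, SimConfig, generate, run_pipeline


@pytest.fixture(scope="session")
def sim():
    """Default-condition synthetic dataset (seed 1)."""
    return generate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def run(sim):
    """Full pipeline output on the default dataset."""
    return run_pipeline(sim, RunConfig(seed=1))


def null_config(seed: int, n_peaks: int = 800, n_genes: int = 200) -> SimConfig:
    """Zero-planted-effect configuration: no DARs, DEGs, contamination,
    center variants or latent co-accessibility; background SNVs only."""
    return SimConfig(
        seed=seed,
        n_chroms=3,
        chrom_length=2_000_000,
        n_peaks=n_peaks,
        n_common_dar=0,
        n_chow_dar=0,
        n_hfd_dar=0,
        n_decoy_peaks=0,
        variant_center_frac={"Common": 0, "Chow": 0, "HFD": 0, "NonDAR": 0},
        background_snv_per_bp=1.0 / 500.0,
        n_contam_samples=0,
        contam_shift=0.0,
        n_marker_genes=0,
        n_marker_peaks=0,
        n_genes=n_genes,
        n_strain_deg=0,
        n_diet_deg=0,
        n_dietstrain_deg=0,
        linked_frac=0.0,
        n_unexpressed=0,
        coacc_sd=0.0,
        n_fp_concordant=0,
        n_fp_discordant=0,
        n_fp_strong=0,
        n_fp_neutral=0,
        n_fp_graded=40,
    )


def random_intervals(
    rng: np.random.Generator, n: int, chroms=("chr1", "chr2", "chr3"),
    max_pos: int = 10_000,
) -> pd.DataFrame:
    starts = rng.integers(0, max_pos, size=n)
    widths = rng.integers(1, 400, size=n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, size=n),
            "start": starts,
            "end": starts + widths,
            "id": [f"iv{i}" for i in range(n)],
        }
    )
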