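"""Shared fixtures: scenes, studies, and the render→measure→derive pipeline."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import pgmorph as pg

SCALE_NM = 10.0


@pytest.fixture
def scale():
    return pg.PixelScale(SCALE_NM, "metadata")


@pytest.fixture
def default_params():
    return pg.PopulationParams()


def _two_arm_design(count_multiplier: float, diameter_multiplier: float,
                    n_images: int, stress_type: str = "toxicity"
                    ) -> pd.DataFrame:
    return pd.DataFrame([
        dict(case_id="ctrl", stress_type=stress_type, level=0,
             count_multiplier=1.0, diameter_multiplier=1.0, grey_shift=0.0,
             n_images=n_images),
        dict(case_id="stress", stress_type=stress_type, level=1,
             count_multiplier=count_multiplier,
             diameter_multiplier=diameter_multiplier, grey_shift=0.0,
             n_images=n_images),
    ])


@pytest.fixture
def two_arm_design():
    return _two_arm_design


def run_pipeline(study: pg.StudyData, *, noise_sd: float = 4.0,
                 image_size: int = 512) -> list[pg.ChloroplastRecord]:
    """Render every scene of a study, measure it, return the records."""
    scale = None
    records = []
    for case_id, scenes in study.scenes.items():
        for j, truth in enumerate(scenes):
            if scale is None:
                scale = pg.PixelScale(truth.nm_per_pixel, "metadata")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # sub-pixel PGs are expected
                img, mask = pg.render_scene(truth, image_size=image_size,
                                            noise_sd=noise_sd, seed=j)
            records.append(pg.measure_scene(
                img, mask, scale, image_id=f"{case_id}_img{j:03d}",
                case_id=case_id))
    return records


@pytest.fixture
def pipeline_runner():
    return run_pipeline


def record_from_truth(truth: pg.SceneGroundTruth, *, image_id: str = "img",
                      chloroplast_id: int = 0,
                      case_id: str | None = None) -> pg.ChloroplastRecord:
    """Build a ChloroplastRecord straight from ground truth (no rendering).

    Pixel areas are the ideal πr² rounded to integers; greys come from the
    scene's configured levels.  Used where the geometry, not the renderer,
    is under test.
    """
    a, b = truth.semi_axes
    ca_px = max(int(round(np.pi * a * b)), 1)
    starch_px = int(round(sum(np.pi * sa * sb
                              for _, _, sa, sb in truth.starch_blobs)))
    pg_px = [max(int(round(np.pi * r ** 2)), 1) for _, _, r in truth.pg_disks]
    return pg.ChloroplastRecord(
        image_id=image_id, chloroplast_id=chloroplast_id, case_id=case_id,
        scale=pg.PixelScale(truth.nm_per_pixel, "metadata"),
        ca_px=ca_px, starch_px=min(starch_px, ca_px - 1),
        pg_px=pg_px,
        pg_greys=[truth.grey_levels["pg"]] * len(pg_px),
        vacuole_grey=truth.grey_levels["vacuole"],
        visibility_fraction=truth.visibility_fraction)


@pytest.fixture
def truth_record():
    return record_from_truth
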