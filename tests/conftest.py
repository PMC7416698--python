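import numpy as np
import pytest

from foveapredict import oct, synth


@pytest.fixture(scope="session")
def default_retina() -> synth.GroundTruthRetina:
    """Mid-range IRD geometry with well-separated bands."""
    return synth.build_retina("S1", "IRD", onl_fovea=100.0, is_fovea=20.0,
                              cos_fovea=27.0, rpe_fovea=18.0)


@pytest.fixture(scope="session")
def noiseless_scan(default_retina) -> oct.BScan:
    scan = synth.render_bscan(default_retina, noise_sd=0.0, n_ascans=192, seed=0)
    return oct.align_to_brm(oct.downsample_lrps(scan, 512))


@pytest.fixture(scope="session")
def noiseless_segmentation(noiseless_scan) -> oct.LayerSegmentation:
    return oct.segment_layers(noiseless_scan)


def make_flat_retina(thicknesses=(100.0, 20.0, 27.0, 18.0), surface_depth=250.0):
    """Retina with laterally constant thicknesses and a flat 'pit' (for
    translation-invariance style tests)."""
    onl, is_, cos, rpe = thicknesses

    def profiles(e):
        e = np.asarray(e, dtype=float)
        ones = np.ones_like(e)
        return onl * ones, is_ * ones, cos * ones, rpe * ones

    def pit(e):
        return surface_depth * np.ones_like(np.asarray(e, dtype=float))

    return synth.GroundTruthRetina(
        subject_id="flat", group="IRD", onl_fovea=onl, is_fovea=is_,
        cos_fovea=cos, rpe_fovea=rpe, pit_profile=pit, thickness_profiles=profiles,
    )


@pytest.fixture()
def flat_retina():
    return make_flat_retina()


def truth_based_cohort_records(cohort, thickness_noise_sd=1.5, seed=0):
    """SubjectRecords built straight from ground truth (no rendering)."""
    return synth.subject_records_from_cohort(
        cohort, thickness_noise_sd=thickness_noise_sd, seed=seed
    )
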