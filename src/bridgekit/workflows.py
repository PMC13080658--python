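"""End-to-end phantom workflows.

Compose the full correlation pipeline — rasterize microscopy, deform,
register back with thin-plate splines, group z, downsample in-plane,
z-normalize the simulated MRI, extract the voxel table and bin by density —
on synthetic scenes with known contrast directions.  Used both as a worked
example and as the self-test of the whole chain.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import BinaryMask, LabelMask, Volume
from .phantom import (
    PhantomScene,
    apply_synthetic_deformation,
    generate_vessel_tree,
    make_tumor_field,
    rasterize_microscopy,
    simulate_mri,
)
from .registration import fit_landmark_transform, resample_volume
from .voxelcorr import (
    bin_by_density,
    downsample_xy_density,
    extract_voxel_table,
    group_z_by_average,
    znormalize_nagm,
)

__all__ = ["density_correlation_phantom"]


def density_correlation_phantom(
    contrast: str = "tumor",
    seed: int = 0,
    micro_spacing: float = 10.0,
    mri_spacing: float = 100.0,
    warp_amplitude: float = 30.0,
    noise_sigma: float = 0.3,
) -> pd.DataFrame:
    """Run the full correlation chain on a phantom with known contrast.

    contrast='tumor' builds a density-gradient lesion with positive
    tumor–T2w coupling (bin means should rise with density);
    contrast='vessel' builds a vascular tree with negative vessel–T2w
    coupling (bin means should fall with vessel volume fraction).

    The microscopy channel is smoothly deformed by ``warp_amplitude`` µm and
    registered back onto the MRI frame by landmark thin-plate splines before
    extraction, so the result exercises rasterization, registration,
    z-grouping, in-plane density downsampling, NAGM normalization,
    extraction and binning together.

    Returns the binned voxel table (column ``density_bin`` plus the
    normalized intensity ``t2w_z``).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if contrast == "tumor":
            extent = (200.0, 400.0, 3200.0)
            scene = PhantomScene([], extent)
            scene.tumor_field = make_tumor_field(extent, micro_spacing, "gradient")
            micro = rasterize_microscopy(
                scene, micro_spacing, channels=("tumor",), seed=seed
            )["tumor"]
            landmark_points = None
            k_vessel, k_tumor = 0.0, 30.0
        elif contrast == "vessel":
            extent = (400.0, 400.0, 400.0)
            scene = generate_vessel_tree(
                extent, n_roots=2, max_depth=3, radius_range=(15.0, 50.0),
                seed=seed,
            )
            mask = rasterize_microscopy(scene, micro_spacing, seed=seed)[
                "vessel_mask"
            ]
            micro = Volume(
                mask.data.astype(float), mask.spacing, mask.origin,
                dtype_role="density",
            )
            landmark_points = scene.bifurcations
            k_vessel, k_tumor = 40.0, 0.0
        else:
            raise ValueError(f"unknown contrast {contrast!r}")

        mri, _ = simulate_mri(
            scene, mri_spacing, "t2w",
            k_vessel=k_vessel, k_tumor=k_tumor,
            noise_sigma=noise_sigma, seed=seed,
        )

        deformed, landmarks, _ = apply_synthetic_deformation(
            micro,
            {"kind": "smooth", "amplitude": warp_amplitude,
             "control_spacing": 2.0 * min(extent)},
            seed=seed,
            landmark_points=landmark_points,
            n_landmarks=15,
        )
        # pull-back map (true frame → deformed frame): swap landmark roles
        registration = fit_landmark_transform(landmarks.swapped(), "tps")
        registered = resample_volume(deformed, registration, micro, "linear")
        registered.dtype_role = "density"

        grouped = group_z_by_average(registered, mri_spacing)
        density = downsample_xy_density(grouped, mri)
        normal = density.data < 0.005
        normalized, _ = znormalize_nagm(
            mri, BinaryMask(normal, mri.spacing, mri.origin)
        )
        categories = LabelMask(
            np.where(normal, 1, 2), mri.spacing, mri.origin
        )
        table = extract_voxel_table(
            {"glioma_density": density, "t2w_z": normalized},
            categories,
            {1: "normal", 2: "lesion"},
        )
        return bin_by_density(table)
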