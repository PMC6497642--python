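"""Field export: CSV point tables and NIfTI volumes on the mask grid."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import TumorGeometry, interior_points, save_mask

__all__ = ["field_table", "field_volume", "save_field_nifti"]


def field_table(points: np.ndarray, phi_e=None, phi_i=None) -> pd.DataFrame:
    """Long-format table (x_cm, y_cm, z_cm, phi_e, phi_i) for CSV export."""
    points = np.atleast_2d(points)
    df = pd.DataFrame(points, columns=["x_cm", "y_cm", "z_cm"])
    if phi_e is not None:
        df["phi_e"] = np.asarray(phi_e)
    if phi_i is not None:
        df["phi_i"] = np.asarray(phi_i)
    return df


def field_volume(geom: TumorGeometry, values: np.ndarray) -> np.ndarray:
    """Scatter per-voxel values (ordered like ``interior_points(geom, 1)``)
    back into a scalar volume aligned with the mask grid; background 0."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != geom.n_foreground:
        raise ValueError(
            f"expected {geom.n_foreground} values (stride-1 interior), got {values.shape[0]}"
        )
    vol = np.zeros(geom.mask.shape)
    vol[geom.mask] = values  # argwhere / boolean indexing share C order
    return vol


def save_field_nifti(geom: TumorGeometry, values: np.ndarray, path) -> None:
    import nibabel as nib

    from .geometry import MM_PER_CM

    affine = np.diag(list(geom.spacing * MM_PER_CM) + [1.0])
    affine[:3, 3] = geom.origin * MM_PER_CM
    nib.save(nib.Nifti1Image(field_volume(geom, values), affine), str(path))
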