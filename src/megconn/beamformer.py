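"""Forward model and LCMV beamformer source reconstruction.

The forward model is the closed-form magnetic field of a current dipole
in a homogeneous conducting sphere (Sarvas solution), which accounts for
both primary and volume currents.  Source time series ("virtual
sensors") are reconstructed with a linearly constrained minimum
variance (LCMV) spatial filter with Tikhonov-regularised data
covariance; the regularisation parameter is expressed as a fraction of
the mean sensor variance (trace(C)/n_channels).  The beamformer is
scalar: per seed the source orientation in the tangent plane is chosen
to maximise output power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeometryError, HeadModel, SourceModel

_MU0_4PI = 1e-7  # T·m/A
_T_TO_FT = 1e15


@dataclass
class BeamformerConfig:
    regularization_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.regularization_fraction < 0:
            raise ValueError("regularization fraction must be >= 0")


def dipole_field(
    seed_position: np.ndarray,
    moment: np.ndarray,
    head_model: HeadModel,
) -> np.ndarray:
    """Magnetic field (fT) of a current dipole at each sensor.

    Parameters
    ----------
    seed_position
        Dipole location, metres, strictly inside the conductor sphere.
    moment
        Dipole moment vector in A·m.

    Returns
    -------
    Field projected on each sensor's orientation, in fT.

    Notes
    -----
    Uses the closed-form solution for a dipole in a homogeneous sphere.
    Radial moments produce zero external field, and a dipole at the
    sphere centre (where every moment is radial) is silent.
    """
    center = head_model.sphere_center
    r0 = np.asarray(seed_position, dtype=float) - center
    if np.linalg.norm(r0) >= head_model.sphere_radius:
        raise GeometryError("dipole must be strictly inside the sphere")
    q = np.asarray(moment, dtype=float)
    r = head_model.sensor_positions - center  # (n, 3)
    rn = np.linalg.norm(r, axis=1)  # |r|
    a_vec = r - r0  # (n, 3)
    an = np.linalg.norm(a_vec, axis=1)  # |a|
    ar = np.einsum("ij,ij->i", a_vec, r)  # a·r
    r0r = r @ r0  # r0·r

    F = an * (rn * an + rn**2 - r0r)
    gradF = (
        (an**2 / rn + ar / an + 2 * an + 2 * rn)[:, None] * r
        - (an + 2 * rn + ar / an)[:, None] * r0[None, :]
    )
    qxr0 = np.cross(q, r0)  # constant vector
    qxr0_dot_r = r @ qxr0
    B = _MU0_4PI / F[:, None] ** 2 * (F[:, None] * qxr0[None, :] - qxr0_dot_r[:, None] * gradF)
    return np.einsum("ij,ij->i", B, head_model.sensor_orientations) * _T_TO_FT


def compute_leadfield(
    head_model: HeadModel,
    seed_position: np.ndarray,
    tangential_frame: np.ndarray,
) -> np.ndarray:
    """Gain matrix (n_sensors, 2) for two tangential unit moments, fT/(A·m)."""
    cols = [dipole_field(seed_position, t, head_model) for t in tangential_frame]
    return np.column_stack(cols)


def compute_leadfields(head_model: HeadModel, source_model: SourceModel) -> np.ndarray:
    """Stacked leadfields, shape (n_seeds, n_sensors, 2)."""
    return np.stack(
        [
            compute_leadfield(head_model, p, f)
            for p, f in zip(source_model.seed_positions, source_model.tangential_frames)
        ]
    )


def pooled_covariance(epochs: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Sensor covariance pooled over epochs (per-epoch demeaning)."""
    epochs = list(epochs)
    if not epochs:
        raise ValueError("need at least one epoch to estimate covariance")
    n_ch = epochs[0].shape[0]
    C = np.zeros((n_ch, n_ch))
    n_total = 0
    for e in epochs:
        d = e - e.mean(axis=1, keepdims=True)
        C += d @ d.T
        n_total += e.shape[1]
    return C / n_total


def lcmv_weights(
    C: np.ndarray,
    leadfields: np.ndarray,
    config: BeamformerConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """LCMV weights for every seed with power-maximising scalar orientation.

    Returns
    -------
    weights : (n_seeds, n_sensors)
        Unit-gain spatial filters (w @ l == 1 per seed).
    orientations : (n_seeds, 2)
        Chosen source orientation in each seed's tangential frame.
    """
    config = config or BeamformerConfig()
    n_ch = C.shape[0]
    lam = config.regularization_fraction * np.trace(C) / n_ch
    C_reg = C + lam * np.eye(n_ch)
    Cinv = np.linalg.inv(C_reg)

    weights = np.empty((leadfields.shape[0], n_ch))
    orientations = np.empty((leadfields.shape[0], 2))
    for k, L in enumerate(leadfields):
        # output power for unit-gain filter along u is 1 / (u' L'C^-1L u);
        # maximise it by taking the smallest-eigenvalue direction.
        M = L.T @ Cinv @ L  # (2, 2)
        evals, evecs = np.linalg.eigh(M)
        u = evecs[:, 0]
        l = L @ u
        Cinv_l = Cinv @ l
        denom = l @ Cinv_l
        if denom <= 0 or not np.isfinite(denom):
            raise np.linalg.LinAlgError(f"degenerate beamformer solution at seed {k}")
        weights[k] = Cinv_l / denom
        orientations[k] = u
    return weights, orientations


def lcmv(
    epochs: list[np.ndarray],
    leadfields: np.ndarray,
    config: BeamformerConfig | None = None,
) -> np.ndarray:
    """Reconstruct virtual-sensor epochs, shape (n_epochs, n_seeds, n_samples)."""
    C = pooled_covariance(epochs)
    W, _ = lcmv_weights(C, leadfields, config)
    return np.stack([W @ e for e in epochs])


def zscore_source_epochs(source_epochs: np.ndarray) -> np.ndarray:
    """Z-score each seed over its concatenated epochs.

    Standardisation is global per seed (not per epoch), so relative
    amplitude differences between epochs are preserved.
    """
    x = np.asarray(source_epochs, dtype=float)
    n_epochs, n_seeds, n_samples = x.shape
    flat = np.moveaxis(x, 1, 0).reshape(n_seeds, n_epochs * n_samples)
    mean = flat.mean(axis=1)
    sd = flat.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant source series cannot be z-scored")
    return (x - mean[None, :, None]) / sd[None, :, None]
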