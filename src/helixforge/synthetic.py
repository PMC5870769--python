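"""Synthetic fit targets with known ground truth.

These are the reference conditions used by the validation suite: each
function returns the generating parameters of a self-built structure
whose parameters are then re-fitted from scratch.  Truth values sit
inside the packaged search ranges but away from their centres, so
recovery is informative.  ``noisy_copy`` adds i.i.d. Gaussian
coordinate noise, emulating the coordinate-level disagreement between
an idealized parametric model and a real structure; it does not emulate
sequence-dependent geometry, bending or irregular termini.
"""

from __future__ import annotations

import numpy as np

from .core import Assembly
from .specifications import (CrickParams, HelixPairParams, SolenoidParams,
                             build_coiled_coil, build_solenoid,
                             build_tropocollagen)

__all__ = [
    "reference_trimer_params", "reference_collagen_params",
    "reference_solenoid_params", "make_reference_trimer",
    "make_reference_collagen", "make_reference_solenoid", "noisy_copy",
]


def reference_trimer_params() -> CrickParams:
    """A parallel coiled-coil trimer (radius 6.5 Å, pitch 150 Å, φCα 10°)."""
    return CrickParams(n_chains=3, superhelix_radius=6.5, pitch=150.0,
                       interface_angle=10.0, n_residues=28)


def reference_collagen_params() -> CrickParams:
    """A collagen triple helix with staggered strands and per-chain spins."""
    return CrickParams(n_chains=3, superhelix_radius=3.0, pitch=85.0,
                       interface_angle=40.0, n_residues=30,
                       z_shift=(0.8, 2.9, 5.0),
                       chain_rotation=(-10.0, 5.0, 20.0),
                       superhelix_handedness="right")


def reference_solenoid_params() -> SolenoidParams:
    """A 5-repeat two-helix solenoid (ankyrin-like geometry)."""
    unit = HelixPairParams(axis_distance=(3.0, 4.5), z_shift=(-1.0, 1.5),
                           phi_ca=(30.0, -60.0), splay=(-12.0, -4.0),
                           off_plane_rotation=(120.0, 240.0),
                           helix_lengths=(10, 10))
    return SolenoidParams(repeat_unit=unit, n_repeats=5, radius=32.0,
                          rise_per_repeat=10.0, twist_per_repeat=12.0)


def make_reference_trimer() -> Assembly:
    return build_coiled_coil(reference_trimer_params())


def make_reference_collagen() -> Assembly:
    return build_tropocollagen(reference_collagen_params())


def make_reference_solenoid() -> Assembly:
    return build_solenoid(reference_solenoid_params())


def noisy_copy(assembly: Assembly, sigma: float, seed: int) -> Assembly:
    """Copy with i.i.d. Gaussian noise (σ per coordinate, Å)."""
    if sigma < 0:
        raise ValueError(f"noise sigma must be >= 0, got {sigma}")
    out = assembly.copy()
    rng = np.random.default_rng(seed)
    coords = out.coordinates()
    out.set_coordinates(coords + rng.normal(0.0, sigma, size=coords.shape))
    return out
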