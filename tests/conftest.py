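import math

import numpy as np
import pytest

from gvshell import builder, geometry, synth


@pytest.fixture(scope="session")
def default_spec() -> geometry.VesicleSpec:
    return geometry.VesicleSpec()


@pytest.fixture(scope="session")
def toy_template() -> builder.MonomerTemplate:
    return synth.make_toy_monomer()


@pytest.fixture(scope="session")
def half_shell(toy_template, default_spec) -> builder.ShellModel:
    return builder.build_half_shell(toy_template, default_spec)


@pytest.fixture(scope="session")
def full_shell(half_shell) -> builder.ShellModel:
    return builder.duplicate_d1(half_shell)


def cylinder_turn_length(r: float, pitch: float) -> float:
    """Closed-form length of one cylindrical helical turn (test oracle)."""
    return math.hypot(2.0 * math.pi * r, pitch)


def cone_arc_oracle(spec: geometry.VesicleSpec, t: float) -> float:
    """Closed-form cone arc length from t_cyl to t (independent oracle).

    With r(t) linear and r_max / t_cap = P sin(alpha), the squared speed is
    P^2 + (2 pi r)^2, whose antiderivative in r is
    G(r) = (r/2) sqrt(P^2 + 4 pi^2 r^2) + (P^2 / 4 pi) asinh(2 pi r / P).
    """
    P = spec.pitch

    def G(r: float) -> float:
        return (r / 2.0) * math.sqrt(P * P + (2 * math.pi * r) ** 2) \
            + (P * P / (4 * math.pi)) * math.asinh(2 * math.pi * r / P)

    r_t = spec.r_max * (1.0 - (t - spec.t_cyl) / spec.t_cap)
    return (spec.t_cap / spec.r_max) * (G(spec.r_max) - G(r_t))


def total_arc_oracle(spec: geometry.VesicleSpec) -> float:
    return spec.t_cyl * cylinder_turn_length(spec.r_max, spec.pitch) \
        + cone_arc_oracle(spec, spec.t_end)


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    """Brute-force full distance matrix (rigidity oracle)."""
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))
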