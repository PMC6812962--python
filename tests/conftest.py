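import numpy as np
import pytest

from hillscape import MWCParameters, RIDGE_POINTS

# printed literature n_H^max column matching RIDGE_POINTS (c, L) pairs
RIDGE_ROWS = tuple(
    (c, L, nh)
    for (c, L), nh in zip(
        RIDGE_POINTS,
        (2.02, 2.28, 2.56, 2.76, 3.06, 3.24, 3.37, 3.44, 3.54),
    )
)

HUMAN_C = 0.01741
HUMAN_L = 3300.0
HUMAN_K_T = 143.0


@pytest.fixture
def human_params() -> MWCParameters:
    """Human-like tetramer on the cooperativity ridge (L c^2 ~ 1)."""
    return MWCParameters.from_c(HUMAN_L, HUMAN_C, HUMAN_K_T)


def naive_mwc_scaled(alpha, L, c):
    """Direct textbook evaluation of the tetramer saturation quotient.

    Independent oracle: raw binding polynomials, no factoring or log-space
    tricks.  Valid only where the polynomials do not overflow.
    """
    alpha = np.asarray(alpha, dtype=float)
    num = alpha * (1 + alpha) ** 3 + L * c * alpha * (1 + c * alpha) ** 3
    den = (1 + alpha) ** 4 + L * (1 + c * alpha) ** 4
    return num / den
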