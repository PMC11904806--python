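"""Small shared numerics: seeds, p-values, ratio-variance weights."""

from __future__ import annotations

import zlib

import numpy as np
from scipy import stats

Z95 = float(stats.norm.ppf(0.975))


def two_sided_p(z: np.ndarray | float) -> np.ndarray | float:
    """Two-sided normal p-value from a z statistic."""
    return 2.0 * stats.norm.sf(np.abs(z))


def derive_seed(master_seed: int, *labels) -> int:
    """Deterministic per-unit seed below 2**31.

    Hashes string labels (protein id, phenotype, cohort...) together with
    the master seed so adding units never perturbs other units' draws.
    """
    h = zlib.crc32(repr(tuple(str(x) for x in labels)).encode())
    return int((master_seed * 1_000_003 + h) % (2**31 - 1))


def ratio_and_variance(
    beta_x: np.ndarray,
    se_x: np.ndarray,
    beta_y: np.ndarray,
    se_y: np.ndarray,
    order: str = "second",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-instrument Wald ratio and its delta-method variance.

    order="first":  var = se_y^2 / beta_x^2
    order="second": var = se_y^2 / beta_x^2 + beta_y^2 * se_x^2 / beta_x^4

    The second-order form propagates uncertainty in the SNP-exposure
    effect and is the package default for inverse-variance weights.
    """
    beta_x = np.asarray(beta_x, dtype=float)
    theta = beta_y / beta_x
    var = np.asarray(se_y, dtype=float) ** 2 / beta_x**2
    if order == "second":
        var = var + np.asarray(beta_y, dtype=float) ** 2 * np.asarray(
            se_x, dtype=float
        ) ** 2 / beta_x**4
    elif order != "first":
        raise ValueError(f"unknown delta order {order!r}")
    return theta, var
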