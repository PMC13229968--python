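"""Token vocabulary: organ tokens, the quantization grid, special tokens.

The vocabulary partitions 228 token IDs into three disjoint ranges:

* ``0–23``   — organ tokens, ID = branching_order × 6 + organ code
               (codes: 0 shoot, 1 internode, 2 petiole, 3–5 leaf slots);
* ``24–222`` — 199 quantized parameter values shared by every parameter;
* ``223–227``— specials (SOS, EOS, META_OPEN, META_CLOSE, PAD).

The parameter grid is the deduplicated sorted union of a small constant set
{0, −10, 10, 90, 1, 3}, a 2.5-degree angle grid covering [−40, 360], and four
10-point linear grids on [0.1, 1], [0.01, 0.1], [0.001, 0.01] and
[0.0001, 0.001] metres, giving comparable relative resolution across the
scales that organ parameters occupy. Quantization snaps a value to the
nearest grid point, breaking exact ties toward the smaller value.

Parameters whose natural range falls outside the grid can register an affine
*prescale*: the value is multiplied by the factor before quantization and
divided by it on decode. By default only ``petiole_curvature`` (range
−200…−50) uses a prescale of 1/10, mapping it onto the 2.5-step region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Vocabulary",
    "build_vocabulary",
    "organ_token",
    "ORGAN_SHOOT",
    "ORGAN_INTERNODE",
    "ORGAN_PETIOLE",
    "ORGAN_LEAF_0",
    "ORGAN_LEAF_1",
    "ORGAN_LEAF_2",
]

# organ codes (trailing digit of the two-digit human-readable organ token)
ORGAN_SHOOT = 0
ORGAN_INTERNODE = 1
ORGAN_PETIOLE = 2
ORGAN_LEAF_0 = 3
ORGAN_LEAF_1 = 4
ORGAN_LEAF_2 = 5

N_ORGAN_TOKENS = 24          # 4 branching orders x 6 organ codes
PARAM_ID_START = N_ORGAN_TOKENS

_TIE_RTOL = 1e-9


class VocabularyError(ValueError):
    """Invalid vocabulary configuration."""


@dataclass
class Vocabulary:
    param_grid: np.ndarray                     # ascending, len 199 by default
    prescale: dict[str, float] = field(default_factory=dict)

    # special token IDs sit immediately after the parameter range
    @property
    def n_params(self) -> int:
        return len(self.param_grid)

    @property
    def param_id_max(self) -> int:
        return PARAM_ID_START + self.n_params - 1

    @property
    def sos(self) -> int:
        return self.param_id_max + 1

    @property
    def eos(self) -> int:
        return self.param_id_max + 2

    @property
    def meta_open(self) -> int:
        return self.param_id_max + 3

    @property
    def meta_close(self) -> int:
        return self.param_id_max + 4

    @property
    def pad(self) -> int:
        return self.param_id_max + 5

    @property
    def size(self) -> int:
        return self.pad + 1

    # ---- classification helpers -------------------------------------------------
    def is_organ(self, tid: int) -> bool:
        return 0 <= tid < N_ORGAN_TOKENS

    def is_param(self, tid: int) -> bool:
        return PARAM_ID_START <= tid <= self.param_id_max

    def is_special(self, tid: int) -> bool:
        return self.param_id_max < tid < self.size

    # ---- quantization -----------------------------------------------------------
    def _factor(self, param_name: str | None) -> float:
        if param_name is None:
            return 1.0
        return self.prescale.get(param_name, 1.0)

    def quantize(self, value: float, param_name: str | None = None) -> int:
        """Token ID of the grid value nearest to ``value`` (after prescale).

        Exact ties between two neighbouring grid points resolve to the
        smaller grid value.
        """
        if not math.isfinite(value):
            raise ValueError(f"cannot quantize non-finite value {value!r}")
        return int(self.quantize_array(np.asarray([value]), param_name)[0])

    def quantize_array(self, values: np.ndarray, param_name: str | None = None) -> np.ndarray:
        values = np.asarray(values, dtype=float) * self._factor(param_name)
        if not np.all(np.isfinite(values)):
            raise ValueError("cannot quantize non-finite values")
        g = self.param_grid
        idx = np.searchsorted(g, values)
        idx = np.clip(idx, 0, len(g) - 1)
        lo = np.clip(idx - 1, 0, len(g) - 1)
        d_hi = np.abs(g[idx] - values)
        d_lo = np.abs(values - g[lo])
        # tie tolerance keeps e.g. 0.0015 -> 0.001 deterministic despite float error
        tol = _TIE_RTOL * np.maximum(1.0, np.abs(values))
        take_lo = (d_lo < d_hi + tol) & (lo < idx)
        out = np.where(take_lo, lo, idx)
        return out + PARAM_ID_START

    def dequantize(self, tid: int, param_name: str | None = None) -> float:
        """Decoded parameter value for a parameter-token ID (inverse prescale)."""
        if not self.is_param(tid):
            raise ValueError(
                f"token ID {tid} is not a parameter token "
                f"(parameter range is {PARAM_ID_START}..{self.param_id_max})")
        return float(self.param_grid[tid - PARAM_ID_START]) / self._factor(param_name)

    def grid_id(self, value: float) -> int:
        """ID of an exact grid value (raises if absent); convenience for tests."""
        i = int(np.searchsorted(self.param_grid, value))
        if i >= len(self.param_grid) or self.param_grid[i] != value:
            raise ValueError(f"{value} is not on the parameter grid")
        return i + PARAM_ID_START


def default_param_grid() -> np.ndarray:
    """The 199-value quantization grid (see module docstring)."""
    constants = np.array([0.0, -10.0, 10.0, 90.0, 1.0, 3.0])
    angles = -40.0 + 2.5 * np.arange(161)                 # [-40, 360] at 2.5 deg
    decimals = np.concatenate([
        np.linspace(0.1, 1.0, 10),
        np.linspace(0.01, 0.1, 10),
        np.linspace(0.001, 0.01, 10),
        np.linspace(0.0001, 0.001, 10),
    ])
    return np.unique(np.concatenate([constants, angles, decimals]))


DEFAULT_PRESCALE = {"petiole_curvature": 0.1}


def build_vocabulary(param_grid: np.ndarray | None = None,
                     prescale: dict[str, float] | None = None) -> Vocabulary:
    """Build the token vocabulary (default: the documented 228-ID layout).

    A custom ``param_grid`` must be strictly increasing and keep the last
    special token ID within an 8-bit-friendly range is not required, but the
    parameter IDs must stay below the special block, i.e. any grid is legal
    as long as it is non-empty and strictly increasing.
    """
    grid = default_param_grid() if param_grid is None else np.asarray(param_grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise VocabularyError("parameter grid must be a non-empty 1-D array")
    if not np.all(np.diff(grid) > 0):
        raise VocabularyError("parameter grid must be strictly increasing")
    return Vocabulary(param_grid=grid,
                      prescale=dict(DEFAULT_PRESCALE if prescale is None else prescale))


def organ_token(branching_order: int, organ_code: int) -> int:
    """Organ token ID: branching_order × 6 + organ code.

    The human-readable form is the two-digit string ``f"{order}{code}"`` —
    e.g. the primary shoot is "00", its internode "01", a secondary-branch
    leaflet "15".
    """
    if not (0 <= branching_order <= 3):
        raise ValueError(f"branching_order {branching_order} outside 0..3")
    if not (0 <= organ_code <= 5):
        raise ValueError(f"organ_code {organ_code} outside 0..5")
    return branching_order * 6 + organ_code
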