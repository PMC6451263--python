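"""Superposition of multichannel MUAP templates at discharge times.

Shared by the simulator (forward synthesis) and the neural feature stage
(reconstruction from spike-triggered-average templates) so both use the
same placement convention: a discharge at sample t places the template
onset at t (offset shifts the onset to t - offset). Templates running past
the end of the signal are truncated identically in both directions.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError


def superpose(
    trains: dict[int, np.ndarray],
    templates: dict[int, np.ndarray],
    n_samples: int,
    offset: int = 0,
) -> np.ndarray:
    """Sum each unit's (n_channels, L) template at its discharge indices.

    Returns a float64 (n_channels, n_samples) array. Spike indices must lie
    in [0, n_samples); template support beyond the signal end is truncated.
    """
    if not templates:
        raise InvalidInputError("empty template bank")
    n_channels, length = next(iter(templates.values())).shape
    out = np.zeros((n_channels, n_samples), dtype=np.float64)

    starts_all: list[np.ndarray] = []
    units_all: list[np.ndarray] = []
    unit_order: list[int] = []
    for uid, idx in trains.items():
        if uid not in templates:
            continue
        idx = np.asarray(idx, dtype=np.int64)
        if idx.size == 0:
            continue
        if idx[0] < 0 or idx[-1] >= n_samples:
            raise InvalidInputError(
                f"unit {uid}: spike index outside [0, {n_samples})"
            )
        starts_all.append(idx - offset)
        units_all.append(np.full(idx.size, len(unit_order), dtype=np.int64))
        unit_order.append(uid)
    if not starts_all:
        return out

    starts = np.concatenate(starts_all)
    unit_rows = np.concatenate(units_all)
    # (n_spikes, L) target sample index per template sample; clip handles
    # truncation at both signal ends, weights for clipped positions are
    # redirected to a scratch bin and dropped.
    pos = starts[:, None] + np.arange(length)[None, :]
    valid = (pos >= 0) & (pos < n_samples)
    pos_clipped = np.where(valid, pos, n_samples)  # scratch bin at the end
    flat_pos = pos_clipped.ravel()

    tmpl_stack = np.stack([templates[uid] for uid in unit_order])  # (U, C, L)
    for ch in range(n_channels):
        weights = tmpl_stack[unit_rows, ch, :].ravel()
        acc = np.bincount(flat_pos, weights=weights, minlength=n_samples + 1)
        out[ch] += acc[:n_samples]
    return out
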