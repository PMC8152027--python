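"""Independent brute-force oracles used by model and alignment tests.

These enumerate CTC paths explicitly and stay deliberately independent of the
recursions they check.
"""

from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

BLANK = 0


def collapse(path: Sequence[int]) -> Tuple[int, ...]:
    """Remove repeats then blanks (the CTC collapse map B)."""
    out = []
    prev = None
    for k in path:
        if k != prev and k != BLANK:
            out.append(k)
        prev = k
    return tuple(out)


_PATH_CACHE: Dict[Tuple[int, int], Dict[Tuple[int, ...], np.ndarray]] = {}


def _paths_by_sequence(T: int, K: int) -> Dict[Tuple[int, ...], np.ndarray]:
    """Map each collapsed sequence to the array of its paths (n_paths x T)."""
    key = (T, K)
    if key not in _PATH_CACHE:
        groups: Dict[Tuple[int, ...], List[Tuple[int, ...]]] = {}
        for path in product(range(K), repeat=T):
            groups.setdefault(collapse(path), []).append(path)
        _PATH_CACHE[key] = {seq: np.array(paths)
                            for seq, paths in groups.items()}
    return _PATH_CACHE[key]


def brute_force_ctc_nll(probs: np.ndarray, target: Sequence[int]) -> float:
    """-ln p(target|x) by explicit path enumeration and collapse."""
    T, K = probs.shape
    paths = _paths_by_sequence(T, K).get(tuple(target))
    if paths is None:
        return np.inf
    path_probs = probs[np.arange(T)[None, :], paths].prod(axis=1)
    return float(-np.log(path_probs.sum()))


def brute_force_best_sequence(probs: np.ndarray) -> Tuple[int, ...]:
    """argmax over collapsed sequences of the summed path probability."""
    T = probs.shape[0]
    best, best_p = (), -1.0
    for seq, paths in _paths_by_sequence(T, probs.shape[1]).items():
        p = probs[np.arange(T)[None, :], paths].prod(axis=1).sum()
        if p > best_p:
            best, best_p = seq, p
    return best


def brute_force_forced_alignment(probs: np.ndarray, target: Sequence[int]
                                 ) -> Optional[List[int]]:
    """Start frames of the most probable path collapsing to `target`.

    Enumerates every frame path, keeps those whose collapse equals the
    target, takes the most probable, and reads off the first frame at which
    each target occurrence is emitted.  Returns None when no path exists.
    """
    T, K = probs.shape
    target = tuple(target)
    best_path, best_p = None, -1.0
    paths = _paths_by_sequence(T, K).get(target)
    if paths is None:
        return None
    path_probs = probs[np.arange(T)[None, :], paths].prod(axis=1)
    best_path = paths[int(np.argmax(path_probs))]
    starts = []
    occ = 0
    prev = BLANK
    for t, k in enumerate(best_path):
        if k != BLANK and k != prev:
            starts.append(t)
            occ += 1
        prev = k
    return starts
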