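"""Per-residue profile prediction and windowed feature assembly.

The classifier input for residue *i* is a 25-dimensional vector: five
per-residue profile channels, each sampled over the window *i−2..i+2*.
The channels, in the fixed order used everywhere in this package, are

====== ================================================
DYNA   backbone dynamics / rigidity (0 flexible, 1 rigid)
SIDE   side-chain dynamics
HELIX  alpha-helix propensity
STRAND beta-strand propensity
COIL   coil propensity
====== ================================================

Channels are themselves predicted from sequence by per-channel linear
regressions over a one-hot windowed encoding (the same construction for
every channel). The backbone-dynamics channel is min–max shifted to [0, 1]
within each sequence before windowing; the other channels pass through raw
by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .seqdata import CANONICAL_AA, Dataset, ProteinRecord

CHANNELS = ("DYNA", "SIDE", "HELIX", "STRAND", "COIL")
N_CHANNELS = len(CHANNELS)
#: residues flanking the target on each side in the feature window
WINDOW_HALF_WIDTH = 2
FEATURE_DIM = N_CHANNELS * (2 * WINDOW_HALF_WIDTH + 1)

_AA_INDEX = {aa: k for k, aa in enumerate(CANONICAL_AA)}

__all__ = [
    "CHANNELS",
    "FEATURE_DIM",
    "WINDOW_HALF_WIDTH",
    "ResidueProfiles",
    "ProfilePredictor",
    "encode_windows",
    "train_profile_predictor",
    "predict_profiles",
    "minmax_shift",
    "normalize_profiles",
    "assemble_features",
    "window_features",
    "featurize_dataset",
    "read_profiles",
    "write_profiles",
]


@dataclass(frozen=True)
class ResidueProfiles:
    """The five per-residue channels for one sequence, as a (5, L) array."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != N_CHANNELS:
            raise ValueError(
                f"profiles must have shape ({N_CHANNELS}, L), got {v.shape}"
            )
        if v.shape[1] < 1:
            raise ValueError("profiles must cover at least one residue")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.values[CHANNELS.index(name)]

    @classmethod
    def from_channels(cls, **channels: Sequence[float]) -> "ResidueProfiles":
        missing = set(CHANNELS) - set(channels)
        if missing:
            raise ValueError(f"missing channels: {sorted(missing)}")
        return cls(np.vstack([np.asarray(channels[c], float) for c in CHANNELS]))


def _clamped_window(length: int, half_width: int) -> np.ndarray:
    """(L, 2w+1) index matrix; out-of-range positions clamp to the termini."""
    offsets = np.arange(-half_width, half_width + 1)
    idx = np.arange(length)[:, None] + offsets[None, :]
    return np.clip(idx, 0, length - 1)


def encode_windows(sequence: str, half_width: int) -> np.ndarray:
    """One-hot windowed encoding of a sequence.

    Row *i* concatenates the one-hot encodings of residues
    *i−w..i+w* (window positions clamped at the termini), giving shape
    ``(L, (2w+1)*20)``. Non-canonical residues (X, B, Z) contribute an
    all-zero block: a neutral encoding.
    """
    length = len(sequence)
    codes = np.array([_AA_INDEX.get(aa, -1) for aa in sequence])
    win = codes[_clamped_window(length, half_width)]  # (L, 2w+1)
    width = 2 * half_width + 1
    enc = np.zeros((length, width * 20))
    rows, cols = np.nonzero(win >= 0)
    enc[rows, cols * 20 + win[rows, cols]] = 1.0
    return enc


@dataclass(frozen=True)
class ProfilePredictor:
    """Per-channel linear regression over a one-hot windowed encoding."""

    half_width: int
    coef: np.ndarray  # (n_channels, (2w+1)*20)
    intercept: np.ndarray  # (n_channels,)
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        expected = (2 * self.half_width + 1) * 20
        coef = np.asarray(self.coef, float)
        if coef.shape != (len(self.channels), expected):
            raise ValueError(
                f"coefficient matrix shape {coef.shape} does not match "
                f"{len(self.channels)} channels x {expected} features"
            )
        object.__setattr__(self, "coef", coef)
        object.__setattr__(
            self, "intercept", np.asarray(self.intercept, float)
        )


#: default half-width of the profile-predictor context window (11 residues)
DEFAULT_PREDICTOR_HALF_WIDTH = 5


def train_profile_predictor(
    records: Sequence[ProteinRecord],
    targets: Mapping[str, np.ndarray],
    half_width: int = DEFAULT_PREDICTOR_HALF_WIDTH,
) -> ProfilePredictor:
    """Fit the five channel regressions by least squares.

    ``targets`` maps record id to a (5, L) array of per-residue channel
    values aligned with that record's sequence. The fit is the minimum-norm
    least-squares solution, so rank-deficient designs (too few sequences,
    low residue diversity) still train, with a warning.
    """
    if not records:
        raise ValueError("need at least one training sequence")
    design = []
    y = []
    for rec in records:
        t = np.asarray(targets[rec.id], float)
        if t.shape != (N_CHANNELS, len(rec)):
            raise ValueError(
                f"targets for {rec.id!r} have shape {t.shape}, expected "
                f"({N_CHANNELS}, {len(rec)})"
            )
        design.append(encode_windows(rec.sequence, half_width))
        y.append(t.T)
    X = np.vstack(design)
    X1 = np.hstack([X, np.ones((X.shape[0], 1))])
    Y = np.vstack(y)
    sol, _res, rank, _sv = np.linalg.lstsq(X1, Y, rcond=None)
    # each one-hot block sums to the intercept column, so full column rank
    # is unattainable by construction; only rank below the structural
    # maximum (19 free levels per window position + intercept) signals a
    # genuinely degenerate design
    width = 2 * half_width + 1
    structural_rank = min(X1.shape[0], width * 19 + 1)
    if rank < structural_rank:
        warnings.warn(
            f"profile-predictor design is degenerate (rank {rank} < "
            f"{structural_rank}); using the minimum-norm solution",
            stacklevel=2,
        )
    return ProfilePredictor(
        half_width=half_width, coef=sol[:-1].T, intercept=sol[-1]
    )


def predict_profiles(
    predictor: ProfilePredictor, sequence: str
) -> ResidueProfiles:
    """Predict the raw (unnormalized) channels for one sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    enc = encode_windows(sequence.upper(), predictor.half_width)
    vals = enc @ predictor.coef.T + predictor.intercept
    return ResidueProfiles(vals.T)


def minmax_shift(values: Sequence[float]) -> np.ndarray:
    """Shift a per-sequence profile into [0, 1] by its own range.

    Returns ``(v − min) / (max − min)``; a constant profile maps to 0.5
    everywhere (degenerate-range convention).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.full_like(v, 0.5)
    return (v - lo) / (hi - lo)


def normalize_profiles(
    profiles: ResidueProfiles, all_channels: bool = False
) -> ResidueProfiles:
    """Apply the per-sequence min–max shift to DYNA (optionally to all)."""
    out = profiles.values.copy()
    for k in range(N_CHANNELS) if all_channels else (0,):
        out[k] = minmax_shift(out[k])
    return ResidueProfiles(out)


def assemble_features(profiles: ResidueProfiles, i: int) -> np.ndarray:
    """The 25-dimensional feature vector for residue ``i`` (0-based).

    Concatenates, channel by channel in the fixed order, the channel values
    at window positions *i−2..i+2*; positions past a terminus clamp to the
    terminal residue's value.
    """
    if not 0 <= i < len(profiles):
        raise IndexError(f"residue index {i} out of range 0..{len(profiles)-1}")
    idx = np.clip(
        np.arange(i - WINDOW_HALF_WIDTH, i + WINDOW_HALF_WIDTH + 1),
        0,
        len(profiles) - 1,
    )
    return profiles.values[:, idx].reshape(-1)


def window_features(profiles: ResidueProfiles) -> np.ndarray:
    """Feature matrix for a whole sequence: shape (L, 25), rows in residue order."""
    idx = _clamped_window(len(profiles), WINDOW_HALF_WIDTH)  # (L, 5)
    # (5, L, 5) -> (L, 5 channels, 5 window) -> (L, 25)
    return profiles.values[:, idx].transpose(1, 0, 2).reshape(len(profiles), -1)


def featurize_dataset(
    dataset: Dataset,
    profiles: Mapping[str, ResidueProfiles] | None = None,
    predictor: ProfilePredictor | None = None,
    normalize_all: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and aligned label vector for a labelled dataset.

    Channels come either from ``profiles`` (precomputed, e.g. read from a
    profile TSV) or are predicted from sequence with ``predictor``; exactly
    one source must be given. Rows are ordered by protein (dataset order),
    then residue, so row counts conserve total residue count.
    """
    if (profiles is None) == (predictor is None):
        raise ValueError("provide exactly one of profiles= or predictor=")
    if not dataset.is_labelled:
        raise ValueError("dataset must be labelled to featurize")
    X_blocks, y_blocks = [], []
    for rec in dataset:
        prof = (
            profiles[rec.id]
            if profiles is not None
            else predict_profiles(predictor, rec.sequence)
        )
        if len(prof) != len(rec):
            raise ValueError(
                f"profiles for {rec.id!r} cover {len(prof)} residues, "
                f"sequence has {len(rec)}"
            )
        prof = normalize_profiles(prof, all_channels=normalize_all)
        X_blocks.append(window_features(prof))
        y_blocks.append(rec.labels)
    return np.vstack(X_blocks), np.concatenate(y_blocks)


def write_profiles(
    profiles: Mapping[str, ResidueProfiles], path
) -> None:
    """Write profiles as a TSV: protein_id, residue_number, channel, value."""
    rows = ["protein_id\tresidue_number\tchannel\tvalue"]
    for pid, prof in profiles.items():
        for c, name in enumerate(CHANNELS):
            for i, v in enumerate(prof.values[c]):
                rows.append(f"{pid}\t{i + 1}\t{name}\t{v:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")


def read_profiles(path, dataset: Dataset) -> dict[str, ResidueProfiles]:
    """Read a profile TSV back into per-record (5, L) arrays."""
    lengths = {r.id: len(r) for r in dataset}
    arrays = {pid: np.full((N_CHANNELS, n), np.nan) for pid, n in lengths.items()}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["protein_id", "residue_number", "channel", "value"]:
            raise ValueError(f"{path}: not a profile table")
        for lineno, line in enumerate(fh, 2):
            pid, pos, name, val = line.rstrip("\n").split("\t")
            if pid not in arrays:
                raise ValueError(f"{path}:{lineno}: unknown protein_id {pid!r}")
            i = int(pos) - 1
            if not 0 <= i < lengths[pid]:
                raise ValueError(
                    f"{path}:{lineno}: residue {pos} out of range for {pid!r}"
                )
            arrays[pid][CHANNELS.index(name), i] = float(val)
    bad = [pid for pid, a in arrays.items() if np.isnan(a).any()]
    if bad:
        raise ValueError(f"{path}: incomplete profiles for {bad}")
    return {pid: ResidueProfiles(a) for pid, a in arrays.items()}
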