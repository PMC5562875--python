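"""Synthetic fixture data with the statistical shape of the training set.

The generator emulates a small pulsed-labelling HDX compilation: ~30
proteins of 56–164 residues (median near 121), about 14% of residues
positive, positives arranged in contiguous runs (early folding residues
sit in nascent secondary-structure elements, not scattered singletons),
and five per-residue profile channels that carry a learnable, noisy signal
about the labels.

Mechanism: each protein gets a latent "foldability" track — smoothed
Gaussian noise plus a hydrophobicity-dependent per-residue offset (early
folding correlates with hydrophobic residues). Residues whose track
exceeds the dataset-wide quantile matched to the target positive fraction
are labelled EARLY; the smoothness of the track makes these threshold
exceedances contiguous runs of a few residues. Each profile channel is a
distinct monotone transform of the track plus independent Gaussian noise,
so the planted signal is learnable but no channel is a label copy.
Everything is reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .features import CHANNELS, N_CHANNELS, ResidueProfiles, encode_windows
from .seqdata import Dataset, ProteinRecord
from .structmetrics import Atom, StructureModel

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_dataset",
    "generate_structure_fixture",
    "generate_labelled_scores",
    "generate_linear_profile_targets",
]

#: background amino-acid frequencies (typical globular-protein composition)
AA_FREQUENCIES = {
    "A": 0.083, "R": 0.055, "N": 0.041, "D": 0.055, "C": 0.014,
    "Q": 0.039, "E": 0.068, "G": 0.071, "H": 0.023, "I": 0.059,
    "L": 0.097, "K": 0.058, "M": 0.024, "F": 0.039, "P": 0.047,
    "S": 0.066, "T": 0.053, "W": 0.011, "Y": 0.029, "V": 0.069,
}

#: Kyte–Doolittle hydropathy, used for the amino-acid-dependent offsets
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults mirror the statistics of the real training compilation:
    30 proteins, lengths 56–164 with median near 121, positive fraction
    0.142 (482 of 3398 residues).
    """

    n_proteins: int = 30
    min_length: int = 56
    max_length: int = 164
    median_length: int = 121
    early_fraction: float = 0.142
    #: scales the latent track's contribution to the profile channels;
    #: 0 gives label-independent pure-noise profiles
    signal_strength: float = 1.0
    #: Gaussian noise s.d. added independently to each profile channel
    profile_noise: float = 0.25
    #: moving-average window of the latent track (controls run lengths)
    smoothing_window: int = 7
    #: scale of the hydrophobicity-dependent offset in the latent track
    hydropathy_weight: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.early_fraction < 1.0:
            raise ValueError(
                f"early_fraction {self.early_fraction} outside (0, 1)"
            )
        if not self.min_length <= self.median_length <= self.max_length:
            raise ValueError("need min_length <= median_length <= max_length")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be non-negative")


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated dataset plus its profiles and generating parameters."""

    dataset: Dataset
    profiles: dict[str, ResidueProfiles]
    latent: dict[str, np.ndarray]
    config: SyntheticConfig

    @property
    def positive_fraction(self) -> float:
        return self.dataset.n_positive / self.dataset.n_residues


def _sample_lengths(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    draws = rng.normal(config.median_length, 28.0, size=config.n_proteins)
    return np.clip(np.rint(draws), config.min_length, config.max_length).astype(int)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(x, pad, mode="reflect")
    return np.convolve(padded, kernel, mode="same")[pad : pad + x.size]


def _latent_track(
    sequence: str, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, len(sequence))
    track = _smooth(noise, config.smoothing_window)
    sd = track.std()
    if sd > 0:
        track = track / sd
    # hydrophobicity acts through local segments, not single residues:
    # smoothing the offsets keeps threshold exceedances in contiguous runs
    offsets = _smooth(
        np.array([KYTE_DOOLITTLE[aa] for aa in sequence]),
        config.smoothing_window,
    )
    return track + config.hydropathy_weight * offsets


# distinct monotone transforms, one per channel, so no channel is a copy
_CHANNEL_TRANSFORMS = {
    "DYNA": lambda t: np.tanh(t),
    "SIDE": lambda t: 0.8 * t,
    "HELIX": lambda t: 1.0 / (1.0 + np.exp(-t)),
    "STRAND": lambda t: np.arcsinh(t),
    "COIL": lambda t: -np.tanh(0.7 * t),  # coil opposes structure formation
}


def generate_dataset(config: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """Generate sequences, labels and profile channels per the config."""
    rng = np.random.default_rng(config.seed)
    aas = np.array(list(AA_FREQUENCIES))
    probs = np.array(list(AA_FREQUENCIES.values()))
    probs = probs / probs.sum()

    lengths = _sample_lengths(config, rng)
    sequences = [
        "".join(rng.choice(aas, size=n, p=probs)) for n in lengths
    ]
    ids = [f"syn{k:03d}" for k in range(config.n_proteins)]
    latent = {
        pid: _latent_track(seq, config, rng)
        for pid, seq in zip(ids, sequences)
    }

    # dataset-wide quantile keeps the realized positive fraction on target
    pooled = np.concatenate([latent[pid] for pid in ids])
    threshold = np.quantile(pooled, 1.0 - config.early_fraction)

    records = []
    profiles: dict[str, ResidueProfiles] = {}
    for pid, seq in zip(ids, sequences):
        track = latent[pid]
        labels = (track >= threshold).astype(np.int8)
        records.append(ProteinRecord(id=pid, sequence=seq, labels=labels))
        chans = np.empty((N_CHANNELS, len(seq)))
        for k, name in enumerate(CHANNELS):
            signal = _CHANNEL_TRANSFORMS[name](config.signal_strength * track)
            chans[k] = signal + rng.normal(0.0, config.profile_noise, len(seq))
        profiles[pid] = ResidueProfiles(chans)
    return SyntheticDataset(
        dataset=Dataset(tuple(records)),
        profiles=profiles,
        latent=latent,
        config=config,
    )


# --- toy structures -------------------------------------------------------

#: atoms placed per residue in fixture structures
FIXTURE_ATOMS_PER_RESIDUE = 5  # N, CA, C, O, H


def _backbone_from_ca(
    ca: np.ndarray, chain: str = "A"
) -> StructureModel:
    """Decorate a C-alpha trace with schematic N, C', O and amide-H atoms."""
    n_res = len(ca)
    atoms = []
    for i in range(n_res):
        u_prev = (
            _safe_unit(ca[i - 1] - ca[i])
            if i > 0
            else -_safe_unit(ca[1] - ca[0])
        )
        u_next = (
            _safe_unit(ca[i + 1] - ca[i])
            if i < n_res - 1
            else -_safe_unit(ca[-1] - ca[-2])
        )
        perp = np.cross(u_prev, u_next)
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(u_prev, np.array([0.0, 0.0, 1.0]))
            if np.linalg.norm(perp) < 1e-8:
                perp = np.array([0.0, 1.0, 0.0])
        perp = _safe_unit(perp)
        pos = {
            "N": ca[i] + 1.46 * u_prev,
            "CA": ca[i],
            "C": ca[i] + 1.52 * u_next,
        }
        pos["O"] = pos["C"] + 1.23 * perp
        pos["H"] = pos["N"] - 1.01 * perp
        for name in ("N", "CA", "C", "O", "H"):
            x, y, z = pos[name]
            atoms.append(
                Atom(
                    chain=chain,
                    residue_number=i + 1,
                    residue_type="ALA",
                    name=name,
                    element="H" if name == "H" else name[0],
                    x=float(x),
                    y=float(y),
                    z=float(z),
                )
            )
    return StructureModel(tuple(atoms))


def _safe_unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def generate_structure_fixture(
    n_residues: int, geometry: str = "ideal_helix"
) -> StructureModel:
    """A toy backbone: ``ideal_helix`` (dense) or ``extended`` (sparse).

    Both geometries place consecutive C-alpha atoms ~3.8 Å apart; the
    helix winds them onto a 2.3 Å-radius, 1.5 Å-rise spiral so its
    neighbourhood is much denser than the extended chain's.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if geometry == "ideal_helix":
        theta = np.deg2rad(100.0) * np.arange(n_residues)
        ca = np.column_stack(
            [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * np.arange(n_residues)]
        )
    elif geometry == "extended":
        dx = math.sqrt(3.8**2 - 1.0)
        ca = np.column_stack(
            [
                dx * np.arange(n_residues),
                np.where(np.arange(n_residues) % 2 == 0, 0.0, 1.0),
                np.zeros(n_residues),
            ]
        )
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return _backbone_from_ca(ca)


# --- score fixtures for the evaluation machinery --------------------------


def generate_labelled_scores(
    n: int, auc_target: float, seed: int = 0, positive_fraction: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Binormal (score, label) samples with a chosen expected AUC.

    Negatives score N(0, 1) and positives N(δ, 1) with
    δ = √2·Φ⁻¹(AUC), whose pair-ranking probability is exactly the target.
    ``auc_target = 1`` uses disjoint uniform score bands instead (the
    binormal δ would be infinite).
    """
    from scipy.stats import norm

    if not 0.5 <= auc_target <= 1.0:
        raise ValueError(f"auc_target {auc_target} outside [0.5, 1]")
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    n_pos = max(1, int(round(n * positive_fraction)))
    n_neg = max(1, n - n_pos)
    labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    if auc_target == 1.0:
        scores = np.concatenate(
            [rng.uniform(0.55, 1.0, n_pos), rng.uniform(0.0, 0.45, n_neg)]
        )
    else:
        delta = math.sqrt(2.0) * norm.ppf(auc_target)
        scores = np.concatenate(
            [rng.normal(delta, 1.0, n_pos), rng.normal(0.0, 1.0, n_neg)]
        )
    perm = rng.permutation(n_pos + n_neg)
    return scores[perm], labels[perm]


def generate_linear_profile_targets(
    records: Sequence[ProteinRecord],
    half_width: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Channel targets exactly (or noisily) linear in the window encoding.

    Returns ``(targets, coef, intercept)`` where ``targets[pid]`` is a
    (5, L) array and ``coef``/``intercept`` are the generating regression
    parameters — the ground truth for profile-predictor recovery tests.
    """
    rng = np.random.default_rng(seed)
    dim = (2 * half_width + 1) * 20
    coef = rng.normal(0.0, 0.3, size=(N_CHANNELS, dim))
    intercept = rng.normal(0.0, 0.5, size=N_CHANNELS)
    targets = {}
    for rec in records:
        enc = encode_windows(rec.sequence, half_width)
        t = enc @ coef.T + intercept
        if noise_sd > 0:
            t = t + rng.normal(0.0, noise_sd, t.shape)
        targets[rec.id] = t.T
    return targets, coef, intercept
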