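"""Seventeen alignment-free ("encoded") genome representations.

Each scheme maps one DNA sequence either to a :class:`Signal` — a
variable-length, possibly multi-channel numeric series — or directly to a
fixed-length :class:`Descriptor` (the k-mer frequency vector and the k-mer
natural vector). Signals are reduced to fixed-length descriptors by the
moment-vector stage (:func:`moment_descriptor`): per channel the mean,
standard deviation and standardized central moments up to order ``J``.

Scheme registry (constants are the values used throughout the genomic
signal-processing literature):

====================  ===========================================================
name                  representation
====================  ===========================================================
``atomic``            per-base atomic number: A=70, T=66, C=58, G=78
``eiip``              electron-ion interaction pseudopotential:
                      C=0.1340, T=0.1335, A=0.1260, G=0.0806
``molmass``           molecular mass: C=110, T=125, A=134, G=150
``freq``              fractional occurrence: C=0.27215, T=0.20576,
                      A=0.24300, G=0.27909
``pam``               pulse-amplitude levels: A=-1.5, G=-0.5, T=1.5, C=0.5
``integer``           C=0, T=1, A=2, G=3
``voss``              four 0/1 indicator channels, one per base
``dinucleotide``      overlapping base pairs on the unit circle at angles
                      2*pi*j/16, lexicographic order; channels (cos, sin)
``iching``            non-overlapping codons -> hexagram index 0-63
                      (two binary lines per base: A=00, C=01, G=10, T=11)
``internucleotide``   distance to the next occurrence of the same base
``minentropy``        sliding-window Shannon entropy (log base 2)
``thermo``            nearest-neighbor dinucleotide enthalpies (kcal/mol,
                      unified NN table of SantaLucia 1998)
``kmer``              overlapping k-mer frequency vector, length 4**k
``triplet``           non-overlapping reading-frame codons, rank 0-63
``kmernv``            k-mer natural vector: (count, mean position, scaled
                      second central moment) per k-mer
``fps``               Fourier power spectrum of each Voss channel, DC excluded
``cgrdft``            chaos-game-representation trajectory as a complex
                      series, DFT power spectrum, DC excluded
====================  ===========================================================

Positions holding ``N`` are handled per scheme class: per-position maps
assign the mean of the four base values; windowed schemes (pairs, codons,
k-mers, entropy windows) drop any window containing an ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.signal import lfilter

from .seqio import SequenceRecord, SequenceSet

__all__ = [
    "SCHEMES",
    "EncodingSpec",
    "Signal",
    "Descriptor",
    "EncodingError",
    "encode",
    "moment_descriptor",
    "descriptor_batch",
]


class EncodingError(ValueError):
    """Sequence unusable for the requested scheme."""


@dataclass(frozen=True)
class Signal:
    """Per-position numeric representation of one sequence."""

    channels: np.ndarray  # shape (n_channels, length)
    channel_names: tuple[str, ...]
    source_id: str

    def __post_init__(self) -> None:
        ch = np.atleast_2d(np.asarray(self.channels, dtype=float))
        object.__setattr__(self, "channels", ch)
        if ch.shape[1] < 1:
            raise EncodingError(f"empty signal for {self.source_id!r}")
        if not np.all(np.isfinite(ch)):
            raise EncodingError(f"non-finite signal values for {self.source_id!r}")
        if len(self.channel_names) != ch.shape[0]:
            raise EncodingError("channel_names length mismatch")


@dataclass(frozen=True)
class Descriptor:
    """Fixed-length numeric vector describing one sequence."""

    values: np.ndarray
    scheme: str
    params: tuple = ()
    source_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise EncodingError(
                f"non-finite descriptor values ({self.scheme}, {self.source_id!r})"
            )

    def __len__(self) -> int:
        return len(self.values)


SCHEMES = (
    "atomic",
    "eiip",
    "molmass",
    "freq",
    "pam",
    "integer",
    "voss",
    "dinucleotide",
    "iching",
    "internucleotide",
    "minentropy",
    "thermo",
    "kmer",
    "triplet",
    "kmernv",
    "fps",
    "cgrdft",
)

#: schemes whose encode() output is already a fixed-length Descriptor
DESCRIPTOR_SCHEMES = frozenset({"kmer", "kmernv"})


@dataclass(frozen=True)
class EncodingSpec:
    """An encoding scheme name plus its scheme-specific parameters.

    Recognized params: ``k`` (kmer, kmernv, internucleotide), ``window``
    (minentropy), ``keep_dc`` (fps, cgrdft).
    """

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in SCHEMES:
            raise EncodingError(
                f"unknown scheme {self.name!r}; choose from {', '.join(SCHEMES)}"
            )
        object.__setattr__(self, "params", dict(self.params))

    def get(self, key: str, default):
        return self.params.get(key, default)

    @property
    def key(self) -> tuple:
        return (self.name, tuple(sorted(self.params.items())))


# per-base value maps (index order A, C, G, T)
_BASE_MAPS = {
    "atomic": np.array([70.0, 58.0, 78.0, 66.0]),
    "eiip": np.array([0.1260, 0.1340, 0.0806, 0.1335]),
    "molmass": np.array([134.0, 110.0, 150.0, 125.0]),
    "freq": np.array([0.24300, 0.27215, 0.27909, 0.20576]),
    "pam": np.array([-1.5, 0.5, -0.5, 1.5]),
    "integer": np.array([2.0, 0.0, 3.0, 1.0]),
}

# Unified nearest-neighbor enthalpies dH (kcal/mol), SantaLucia 1998; the 10
# unique stacks extended to all 16 dinucleotides by reverse-complement
# symmetry. Order: AA AC AG AT CA CC CG CT GA GC GG GT TA TC TG TT.
NN_ENTHALPY = {
    "AA": -7.9, "AC": -8.4, "AG": -7.8, "AT": -7.2,
    "CA": -8.5, "CC": -8.0, "CG": -10.6, "CT": -7.8,
    "GA": -8.2, "GC": -9.8, "GG": -8.0, "GT": -8.4,
    "TA": -7.2, "TC": -8.2, "TG": -8.5, "TT": -7.9,
}

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# CGR corners, Jeffrey's convention
_CGR_CORNERS = np.array(
    [0.0 + 0.0j, 0.0 + 1.0j, 1.0 + 1.0j, 1.0 + 0.0j]  # A, C, G, T
)


def _codes(rec: SequenceRecord) -> np.ndarray:
    seq = rec.seq.replace("-", "")
    if not seq:
        raise EncodingError(f"record {rec.id!r} empty after gap removal")
    return np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=len(seq))


def _require(codes: np.ndarray, minimum: int, scheme: str, rec_id: str) -> None:
    if len(codes) < minimum:
        raise EncodingError(
            f"record {rec_id!r} has length {len(codes)} < minimum {minimum} "
            f"for scheme {scheme!r}"
        )


def _per_position(codes: np.ndarray, table: np.ndarray) -> np.ndarray:
    # N -> mean of the four mapped values
    full = np.append(table, table.mean())
    return full[codes]


def _window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Ranks of all length-k windows (base-4, A<C<G<T) and their validity mask."""
    n = len(codes)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = np.all(win < 4, axis=1)
    pow4 = 4 ** np.arange(k - 1, -1, -1)
    ranks = (win.astype(np.int64) * pow4).sum(axis=1)
    ranks[~valid] = -1
    return ranks, valid


def _voss(codes: np.ndarray) -> np.ndarray:
    ch = np.zeros((4, len(codes)))
    for b in range(4):
        ch[b, codes == b] = 1.0
    ch[:, codes == 4] = 0.25
    return ch


def _cgr_trajectory(codes: np.ndarray) -> np.ndarray:
    corners = np.append(_CGR_CORNERS, 0.5 + 0.5j)  # N -> center (corner mean)
    w = corners[codes]
    # X_n = (X_{n-1} + W_n) / 2 with X_0 = (1/2, 1/2)
    x0 = 0.5 + 0.5j
    traj, _ = lfilter([0.5], [1.0, -0.5], w, zi=[0.5 * x0])
    return traj


def _internucleotide(codes: np.ndarray, k: int) -> np.ndarray:
    n = len(codes)
    out = np.zeros(n)
    # next occurrence of the same base at positions i+k, i+2k, ... ; scan
    # backwards per residue class keeping the last index seen per base
    last = np.full((k, 5), -1, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        b = codes[i]
        r = i % k
        if b != 4:
            j = last[r, b]
            if j >= 0:
                out[i] = j - i
            last[r, b] = i
    return out


def _entropy_windows(codes: np.ndarray, w: int) -> np.ndarray:
    n = len(codes)
    onehot = np.zeros((5, n))
    onehot[codes, np.arange(n)] = 1.0
    csum = np.concatenate([np.zeros((5, 1)), np.cumsum(onehot, axis=1)], axis=1)
    counts = csum[:, w:] - csum[:, :-w]  # (5, n-w+1)
    valid = counts[4] == 0
    if not np.any(valid):
        raise EncodingError("every entropy window contains an N")
    c = counts[:4, valid]
    p = c / w
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(p), 0.0)
    return terms.sum(axis=0)


def _kmer_counts(codes: np.ndarray, k: int) -> np.ndarray:
    ranks, valid = _window_codes(codes, k)
    return np.bincount(ranks[valid], minlength=4**k).astype(float)


def _kmer_natural_vector(codes: np.ndarray, k: int) -> np.ndarray:
    """(count, mean 1-based slot position, scaled 2nd central moment) per k-mer.

    The second moment is D2_w = sum_i (p_i - mu_w)^2 / (n_w * N) with N the
    number of k-mer slots; D2_w = 0 when a k-mer occurs at most once.
    """
    ranks, valid = _window_codes(codes, k)
    positions = np.arange(1, len(ranks) + 1, dtype=float)
    r, p = ranks[valid], positions[valid]
    n_slots = len(r)
    if n_slots == 0:
        raise EncodingError("no N-free k-mer windows in sequence")
    m = 4**k
    counts = np.bincount(r, minlength=m).astype(float)
    pos_sum = np.bincount(r, weights=p, minlength=m)
    pos_sq = np.bincount(r, weights=p * p, minlength=m)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(counts > 0, pos_sum / np.maximum(counts, 1), 0.0)
        ss = pos_sq - counts * mu * mu  # sum (p - mu)^2
        d2 = np.where(counts > 1, ss / (np.maximum(counts, 1) * n_slots), 0.0)
    d2 = np.clip(d2, 0.0, None)  # guard roundoff
    return np.concatenate([counts, mu, d2])


def _power_spectrum(x: np.ndarray, keep_dc: bool) -> np.ndarray:
    spec = np.abs(np.fft.fft(x)) ** 2
    return spec if keep_dc else spec[1:]


def encode(spec: EncodingSpec, rec: SequenceRecord) -> Union[Signal, Descriptor]:
    """Encode one sequence under ``spec``.

    Returns a :class:`Signal` for the fifteen signal-valued schemes and a
    :class:`Descriptor` for ``kmer`` and ``kmernv``. Deterministic: identical
    (spec, sequence) pairs give bit-identical output.
    """
    name = spec.name
    codes = _codes(rec)

    if name in _BASE_MAPS:
        _require(codes, 1, name, rec.id)
        return Signal(_per_position(codes, _BASE_MAPS[name])[None, :], (name,), rec.id)

    if name == "voss":
        _require(codes, 1, name, rec.id)
        return Signal(_voss(codes), ("A", "C", "G", "T"), rec.id)

    if name == "dinucleotide":
        _require(codes, 2, name, rec.id)
        ranks, valid = _window_codes(codes, 2)
        if not np.any(valid):
            raise EncodingError(f"record {rec.id!r}: no N-free dinucleotides")
        theta = 2.0 * np.pi * ranks[valid] / 16.0
        return Signal(np.vstack([np.cos(theta), np.sin(theta)]), ("cos", "sin"), rec.id)

    if name in ("iching", "triplet"):
        _require(codes, 3, name, rec.id)
        n_codons = len(codes) // 3
        tri = codes[: 3 * n_codons].reshape(n_codons, 3)
        valid = np.all(tri < 4, axis=1)
        if not np.any(valid):
            raise EncodingError(f"record {rec.id!r}: no N-free codons")
        vals = (tri[valid].astype(np.int64) * np.array([16, 4, 1])).sum(axis=1)
        return Signal(vals[None, :].astype(float), (name,), rec.id)

    if name == "internucleotide":
        k = int(spec.get("k", 1))
        if k < 1:
            raise EncodingError("internucleotide stride k must be >= 1")
        _require(codes, 1, name, rec.id)
        return Signal(_internucleotide(codes, k)[None, :], (name,), rec.id)

    if name == "minentropy":
        w = int(spec.get("window", 12))
        if w < 1:
            raise EncodingError("minentropy window must be >= 1")
        _require(codes, w, name, rec.id)
        return Signal(_entropy_windows(codes, w)[None, :], ("H",), rec.id)

    if name == "thermo":
        _require(codes, 2, name, rec.id)
        ranks, valid = _window_codes(codes, 2)
        if not np.any(valid):
            raise EncodingError(f"record {rec.id!r}: no N-free dinucleotides")
        bases = "ACGT"
        table = np.array(
            [NN_ENTHALPY[a + b] for a in bases for b in bases]
        )
        return Signal(table[ranks[valid]][None, :], ("dH",), rec.id)

    if name == "kmer":
        k = int(spec.get("k", 3))
        _require(codes, k, name, rec.id)
        counts = _kmer_counts(codes, k)
        total = counts.sum()
        if total == 0:
            raise EncodingError(f"record {rec.id!r}: no N-free {k}-mers")
        return Descriptor(counts / total, "kmer", (("k", k),), rec.id)

    if name == "kmernv":
        k = int(spec.get("k", 3))
        _require(codes, k, name, rec.id)
        return Descriptor(_kmer_natural_vector(codes, k), "kmernv", (("k", k),), rec.id)

    if name == "fps":
        _require(codes, 2, name, rec.id)
        keep_dc = bool(spec.get("keep_dc", False))
        spectra = np.vstack([_power_spectrum(ch, keep_dc) for ch in _voss(codes)])
        return Signal(spectra, ("A", "C", "G", "T"), rec.id)

    if name == "cgrdft":
        _require(codes, 2, name, rec.id)
        keep_dc = bool(spec.get("keep_dc", False))
        traj = _cgr_trajectory(codes)
        return Signal(_power_spectrum(traj, keep_dc)[None, :], ("power",), rec.id)

    raise EncodingError(f"unknown scheme {name!r}")  # pragma: no cover


def cgr_trajectory(rec: SequenceRecord) -> np.ndarray:
    """CGR points of a sequence as an (n, 2) array (exposed for inspection)."""
    traj = _cgr_trajectory(_codes(rec))
    return np.column_stack([traj.real, traj.imag])


def moment_descriptor(signal: Signal, J: int = 4) -> Descriptor:
    """Reduce a signal to per-channel moment vectors.

    Each channel contributes (mean, population standard deviation,
    standardized central moments of order 3..J); channels are concatenated,
    so the descriptor length is ``n_channels * J``. Standardized moments of
    a constant channel (sigma = 0) are defined as 0.
    """
    if J < 2:
        raise EncodingError(f"moment order J must be >= 2, got {J}")
    out = []
    for ch in signal.channels:
        mu = float(ch.mean())
        sd = float(ch.std())
        out.extend([mu, sd])
        for j in range(3, J + 1):
            if sd == 0.0:
                out.append(0.0)
            else:
                out.append(float(np.mean(((ch - mu) / sd) ** j)))
    return Descriptor(np.array(out), f"moments(J={J})", (("J", J),), signal.source_id)


def _resample_spectrum(signal: Signal, m: int) -> Descriptor:
    """Evenly rescale each power-spectrum channel to length ``m``."""
    out = []
    for ch in signal.channels:
        src = np.linspace(0.0, 1.0, num=len(ch))
        dst = np.linspace(0.0, 1.0, num=m)
        out.append(np.interp(dst, src, ch))
    return Descriptor(
        np.concatenate(out), f"spectrum(m={m})", (("m", m),), signal.source_id
    )


def descriptor_batch(
    spec: EncodingSpec,
    seqs: SequenceSet,
    J: int = 4,
    m: int | None = None,
) -> list[Descriptor]:
    """Fixed-length descriptors for every sequence in a set.

    Signal-valued schemes go through :func:`moment_descriptor`;
    descriptor-valued schemes (kmer, kmernv) pass through unchanged. For the
    spectral schemes (fps, cgrdft) an even rescaling of the spectrum to
    length ``m`` is available as an alternative descriptor.
    """
    out = []
    for rec in seqs:
        try:
            enc = encode(spec, rec)
        except EncodingError as exc:
            raise EncodingError(f"[{spec.name}] {rec.id}: {exc}") from exc
        if isinstance(enc, Descriptor):
            out.append(enc)
        elif m is not None and spec.name in ("fps", "cgrdft"):
            out.append(_resample_spectrum(enc, m))
        else:
            out.append(moment_descriptor(enc, J=J))
    lengths = {len(d) for d in out}
    if len(lengths) > 1:  # pragma: no cover - defended by scheme definitions
        raise EncodingError(
            f"[{spec.name}] descriptors have mixed lengths {sorted(lengths)}"
        )
    return out
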