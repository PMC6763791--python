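"""Ground-truthed synthetic inputs for every pipeline stage.

The AP-MS generator emulates the statistical structure the analysis
assumes: a log-normal population of unspecific binders whose latent
abundance is shared between the bait and control arms (so their log2
ratios form a single Gaussian mode near zero), mean-one multiplicative
log-normal replicate noise (so arm expectations are exact and within-arm
replicates correlate with r > 0.9 at the default noise level), a minority
of spiked true interactors whose bait-arm expectation is the control
expectation times 2**fc, and bait-exclusive proteins with all-zero control
intensities. Unique-peptide counts are drawn independently of intensity.

Everything is reproducible: a fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colocalization import ImagePair
from .errors import ConfigurationError, GenerationError
from .quant_io import AMINO_ACIDS, QuantTable

LABELS = ("background", "interactor", "exclusive")


@dataclass
class SimConfig:
    """Generative parameters of a synthetic pulldown experiment.

    ``background_log_mean``/``background_log_sd`` parameterize the natural-log
    intensity of unspecific binders (defaults put intensities around 1.2e6,
    comfortably above the reporting floor). ``replicate_cv`` is the
    multiplicative coefficient of variation of replicate noise;
    ``interactor_log2_fc_range`` spikes fold changes well beyond the
    background mode so that called and true interactors can be compared.
    """

    n_background: int = 500
    n_interactors: int = 50
    n_exclusive: int = 6
    n_replicates: int = 3
    background_log_mean: float = 14.0
    background_log_sd: float = 1.5
    replicate_cv: float = 0.25
    interactor_log2_fc_range: tuple[float, float] = (3.0, 8.0)
    intensity_floor: float = 1000.0
    dropout_below_floor: bool = False
    peptide_count_range: tuple[int, int] = (1, 30)
    seed: int = 0

    def validate(self) -> None:
        for fld in ("n_background", "n_interactors", "n_exclusive"):
            if getattr(self, fld) < 0:
                raise ConfigurationError(f"{fld} must be >= 0")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if self.replicate_cv <= 0:
            raise ConfigurationError("replicate_cv must be > 0")
        lo, hi = self.interactor_log2_fc_range
        if not lo < hi:
            raise ConfigurationError("interactor_log2_fc_range low must be < high")
        if self.background_log_sd <= 0:
            raise ConfigurationError("background_log_sd must be > 0")
        if self.intensity_floor < 0:
            raise ConfigurationError("intensity_floor must be >= 0")
        pmin, pmax = self.peptide_count_range
        if pmin < 0 or pmin > pmax:
            raise ConfigurationError("peptide_count_range must satisfy 0 <= min <= max")
        if self.n_background + self.n_interactors + self.n_exclusive == 0:
            raise ConfigurationError("n_background + n_interactors + n_exclusive must be > 0")


@dataclass
class SimTruth:
    """Ground-truth class and spiked effect per generated protein."""

    labels: dict[str, str] = field(default_factory=dict)
    true_log2_fc: dict[str, float] = field(default_factory=dict)

    def of_label(self, label: str) -> list[str]:
        return [a for a, l in self.labels.items() if l == label]


def _noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with coefficient of variation cv."""
    s = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def generate_apms_dataset(config: SimConfig) -> tuple[QuantTable, SimTruth]:
    """Generate a replicate bait/control intensity table plus its truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.n_replicates

    accs: list[str] = []
    labels: list[str] = []
    bait_rows: list[np.ndarray] = []
    ctrl_rows: list[np.ndarray] = []
    fcs: list[float] = []

    def add(acc: str, label: str, bait_latent: float, ctrl_latent: float | None, fc: float):
        accs.append(acc)
        labels.append(label)
        fcs.append(fc)
        bait_rows.append(math.exp(bait_latent) * _noise(rng, config.replicate_cv, k))
        if ctrl_latent is None:
            ctrl_rows.append(np.zeros(k))
        else:
            ctrl_rows.append(math.exp(ctrl_latent) * _noise(rng, config.replicate_cv, k))

    for i in range(config.n_background):
        latent = rng.normal(config.background_log_mean, config.background_log_sd)
        add(f"BG{i:05d}", "background", latent, latent, 0.0)
    lo, hi = config.interactor_log2_fc_range
    for i in range(config.n_interactors):
        latent = rng.normal(config.background_log_mean, config.background_log_sd)
        fc = rng.uniform(lo, hi)
        add(f"INT{i:04d}", "interactor", latent + fc * math.log(2.0), latent, fc)
    for i in range(config.n_exclusive):
        latent = rng.normal(config.background_log_mean, config.background_log_sd)
        add(f"EXC{i:03d}", "exclusive", latent, None, math.inf)

    bait = np.vstack(bait_rows) if bait_rows else np.empty((0, k))
    control = np.vstack(ctrl_rows) if ctrl_rows else np.empty((0, k))
    if config.dropout_below_floor:
        bait = np.where(bait < config.intensity_floor, 0.0, bait)
        control = np.where(control < config.intensity_floor, 0.0, control)

    pmin, pmax = config.peptide_count_range
    peptides = rng.integers(pmin, pmax + 1, size=len(accs))
    meta = pd.DataFrame(
        {
            "entry_name": [f"{a}_SIM" for a in accs],
            "protein_name": [f"synthetic {l} protein {a}" for a, l in zip(accs, labels)],
            "unique_peptides": peptides,
        },
        index=pd.Index(accs, name="accession"),
    )
    table = QuantTable(meta=meta, bait=bait, control=control)
    truth = SimTruth(
        labels=dict(zip(accs, labels)),
        true_log2_fc=dict(zip(accs, fcs)),
    )
    return table, truth


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def generate_sequences(
    n: int,
    length_range: tuple[int, int] = (100, 600),
    seed: int = 0,
    frequencies: dict[str, float] | None = None,
) -> dict[str, str]:
    """Random amino-acid sequences (uniform residue distribution by default)."""
    lo, hi = length_range
    if lo < 20:
        raise ConfigurationError("length_range min must be >= 20")
    if lo > hi:
        raise ConfigurationError("length_range min must be <= max")
    rng = np.random.default_rng(seed)
    alphabet = list(AMINO_ACIDS)
    if frequencies is None:
        p = np.full(len(alphabet), 1.0 / len(alphabet))
    else:
        p = np.array([frequencies.get(a, 0.0) for a in alphabet])
        if not math.isclose(p.sum(), 1.0, rel_tol=1e-6):
            raise ConfigurationError("frequencies must sum to 1 over the 20-letter alphabet")
    out: dict[str, str] = {}
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        out[f"SEQ{i:05d}"] = "".join(rng.choice(alphabet, size=length, p=p))
    return out


_FILLER_ALPHABET = "ACDEFGHILMNQSTVWY"  # no K/R (no cleavage sites), no P


def generate_scaffold_with_peptides(
    peptides: list[str], length: int, seed: int = 0
) -> str:
    """Synthetic protein scaffold embedding given peptides as tryptic fragments.

    Builds a sequence of exactly ``length`` residues in which each peptide
    occurs exactly once and is released intact by a zero-missed-cleavage
    tryptic digest: each peptide is preceded by a lysine separator and the
    filler alphabet contains no K/R/P. A stand-in for a real protein
    sequence that cannot be bundled; labelled synthetic by construction.
    """
    for p in peptides:
        if not p or p[-1] not in "KR":
            raise GenerationError(f"peptide {p!r} must end in K or R")
        if p[0] == "P":
            raise GenerationError(f"peptide {p!r} must not start with P")
        for i in range(len(p) - 1):
            if p[i] in "KR" and p[i + 1] != "P":
                raise GenerationError(
                    f"peptide {p!r} has an internal tryptic cleavage site"
                )
    core = sum(len(p) for p in peptides) + len(peptides)  # + one K separator each
    filler_total = length - core
    if filler_total < len(peptides) + 1:
        raise GenerationError(
            f"length {length} too small for {len(peptides)} peptides (need >= {core + len(peptides) + 1})"
        )
    rng = np.random.default_rng(seed)
    # split filler into n_peps + 1 chunks, each >= 1 residue
    n_chunks = len(peptides) + 1
    extra = filler_total - n_chunks
    sizes = 1 + rng.multinomial(extra, np.full(n_chunks, 1.0 / n_chunks))

    def filler(sz: int) -> str:
        return "".join(rng.choice(list(_FILLER_ALPHABET), size=sz))

    parts = [filler(int(sizes[0]))]
    for pep, sz in zip(peptides, sizes[1:]):
        parts.append("K")
        parts.append(pep)
        parts.append(filler(int(sz)))
    seq = "".join(parts)
    assert len(seq) == length
    return seq


# ---------------------------------------------------------------------------
# image pairs
# ---------------------------------------------------------------------------


def _sphere_offsets(radius: int) -> np.ndarray:
    r = radius
    zz, yy, xx = np.mgrid[-r: r + 1, -r: r + 1, -r: r + 1]
    return np.argwhere(zz**2 + yy**2 + xx**2 <= r * r) - r


def generate_image_pair(
    shape: tuple[int, int, int],
    n_vesicles: int = 10,
    overlap_fraction: float = 0.5,
    background_level: float = 0.0,
    seed: int = 0,
    radius: int = 2,
    amplitude: float = 1000.0,
) -> tuple[ImagePair, float]:
    """Two-channel stack of identical solid spherical vesicles.

    Channel 1 holds ``n_vesicles`` spheres; a fraction ``overlap_fraction``
    of them (rounded to whole vesicles) is co-located with channel-2
    spheres, and channel 2 additionally carries its own disjoint spheres,
    so exactly that fraction of channel-1 signal mass lies inside
    channel-2-positive regions. Returns the pair and the realized overlap
    fraction (n_overlap / n_vesicles).
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ConfigurationError("overlap_fraction must be in [0, 1]")
    if n_vesicles < 1:
        raise ConfigurationError("n_vesicles must be >= 1")
    rng = np.random.default_rng(seed)
    n_overlap = int(round(overlap_fraction * n_vesicles))
    n_extra_ch2 = n_vesicles - n_overlap
    n_total = n_vesicles + n_extra_ch2

    margin = radius + 2
    min_sep = 2 * radius + 4  # keeps sphere supports (and halos) disjoint
    dims = np.array(shape)
    if np.any(dims <= 2 * margin):
        raise GenerationError(f"shape {shape} too small for vesicles of radius {radius}")

    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_total:
        tries += 1
        if tries > 20000:
            raise GenerationError(
                f"could not place {n_total} vesicles in shape {shape}"
            )
        c = np.array([rng.integers(margin, d - margin) for d in dims])
        if all(np.abs(c - prev).max() >= min_sep for prev in centers):
            centers.append(c)

    ch1 = np.full(shape, float(background_level))
    ch2 = np.full(shape, float(background_level))
    offsets = _sphere_offsets(radius)

    def paint(img: np.ndarray, center: np.ndarray) -> None:
        vox = offsets + center
        img[vox[:, 0], vox[:, 1], vox[:, 2]] = amplitude + background_level

    for c in centers[:n_vesicles]:
        paint(ch1, c)
    for c in centers[:n_overlap]:
        paint(ch2, c)
    for c in centers[n_vesicles:]:
        paint(ch2, c)

    true_overlap = n_overlap / n_vesicles
    return ImagePair(ch1=ch1, ch2=ch2), true_overlap
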