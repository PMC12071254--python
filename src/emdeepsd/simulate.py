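"""Synthetic end-motif data with the reported cancer-vs-control structure.

Real plasma cfDNA end-motif cohorts are controlled-access, so this module
generates profile matrices that reproduce the *direction* of the cancer
shift — thymine-prefixed motifs up-regulated, cytosine-prefixed motifs
down-regulated — on top of a smooth, deterministic control baseline. The
generative model is logistic-normal: class log-baselines receive i.i.d.
Gaussian noise per sample and motif and are renormalised to the simplex,
which keeps per-motif dispersion tunable independently of the mean. It
emulates compositional profiles with class mean shifts; it does not
emulate sequencing-depth sampling noise, batch effects, or inter-motif
covariance of real cohorts.

Toy fragment/reference fixtures for the extractor and a synthetic
founder-profile matrix are also provided, so every stage of the pipeline
is testable without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .diversity import FounderMatrix
from .motifs import MOTIFS, ProfileMatrix, revcomp

#: the ten most strongly shifted motifs (five up in cancer, five down)
TOP_UP_MOTIFS = ("TAAA", "TGGA", "TGGC", "TGGG", "TGGT")
TOP_DOWN_MOTIFS = ("CCCA", "CCCT", "CCTC", "CCTT", "CTTT")

T_PREFIXED = tuple(m for m in MOTIFS if m.startswith("T"))
C_PREFIXED = tuple(m for m in MOTIFS if m.startswith("C"))


@dataclass
class SimulationConfig:
    """Study conditions for a simulated cancer/control cohort.

    ``effect_size`` is a symmetric log-scale shift: up-motifs are
    multiplied by exp(effect) and down-motifs by exp(-effect) in the
    cancer baseline before renormalisation. ``concentration`` controls
    sample-level dispersion; per-motif log-frequency noise has standard
    deviation 1/sqrt(concentration) (default 50, i.e. ~14% coefficient
    of variation, a visually realistic spread for 256-bin profiles).
    """

    n_cancer: int = 50
    n_control: int = 50
    effect_size: float = 0.5
    concentration: float = 50.0
    up_motifs: tuple[str, ...] = T_PREFIXED
    down_motifs: tuple[str, ...] = C_PREFIXED
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cancer < 1 or self.n_control < 1:
            raise ValueError("need at least one sample per group")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.effect_size > 0 and not (self.up_motifs or self.down_motifs):
            raise ValueError("effect_size > 0 requires non-empty motif sets")


#: per-position base propensities of the control baseline. Healthy plasma
#: cfDNA ends are strongly cytosine-dominated at the first position
#: (nuclease-driven cleavage preference, CCC-prefixed motifs most
#: frequent); the cancer shift erodes this dominance, which is why motif
#: diversity rises in cancer.
_POSITION_WEIGHTS = (
    {"A": 0.19, "C": 0.45, "G": 0.15, "T": 0.21},
    {"A": 0.26, "C": 0.28, "G": 0.21, "T": 0.25},
    {"A": 0.26, "C": 0.25, "G": 0.22, "T": 0.27},
    {"A": 0.25, "C": 0.26, "G": 0.23, "T": 0.26},
)


def control_baseline() -> np.ndarray:
    """Smooth deterministic 256-motif control distribution (sums to 1)."""
    p = np.array(
        [
            np.prod([_POSITION_WEIGHTS[i][b] for i, b in enumerate(m)])
            for m in MOTIFS
        ]
    )
    return p / p.sum()


def cancer_baseline(cfg: SimulationConfig) -> np.ndarray:
    """Control baseline with the log-scale cancer shift applied."""
    p = control_baseline()
    up = [MOTIFS.index(m) for m in cfg.up_motifs]
    down = [MOTIFS.index(m) for m in cfg.down_motifs]
    p = p.copy()
    p[up] *= np.exp(cfg.effect_size)
    p[down] *= np.exp(-cfg.effect_size)
    return p / p.sum()


def simulate_profiles(cfg: SimulationConfig) -> ProfileMatrix:
    """Draw a labelled cohort of logistic-normal profiles (label 1 = cancer)."""
    rng = np.random.RandomState(cfg.seed)
    sigma = 1.0 / np.sqrt(cfg.concentration)
    log_control = np.log(control_baseline())
    log_cancer = np.log(cancer_baseline(cfg))
    rows, labels, ids = [], [], []
    for i in range(cfg.n_control):
        logp = log_control + sigma * rng.standard_normal(256)
        p = np.exp(logp - logp.max())
        rows.append(p / p.sum())
        labels.append(0)
        ids.append(f"control_{i:04d}")
    for i in range(cfg.n_cancer):
        logp = log_cancer + sigma * rng.standard_normal(256)
        p = np.exp(logp - logp.max())
        rows.append(p / p.sum())
        labels.append(1)
        ids.append(f"cancer_{i:04d}")
    return ProfileMatrix(sample_ids=ids, values=np.array(rows),
                         labels=np.array(labels))


_FRAG_LEN = 12  # watson window [s, s+4), free middle, crick window [s+8, s+12)


def simulate_fragments(
    target_profile: np.ndarray,
    n_fragments: int,
    seed: int,
    out_dir: str | Path,
    chrom: str = "chrSim",
) -> tuple[Path, Path]:
    """Plant fragments on a synthetic reference so that extraction
    recovers ``target_profile``.

    Each fragment is a disjoint 12 bp span whose two 5'-end 4-mers are
    drawn i.i.d. from the target distribution (the crick motif is written
    as its reverse complement at the right end of the span). Writes
    ``reference.fa`` and ``fragments.bed`` to ``out_dir`` and returns
    their paths; output is byte-identical per seed.
    """
    target = np.asarray(target_profile, dtype=float)
    if target.size != 256 or (target < 0).any():
        raise ValueError("target profile must be 256 non-negative frequencies")
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    target = target / target.sum()
    rng = np.random.RandomState(seed)
    watson_idx = rng.choice(256, size=n_fragments, p=target)
    crick_idx = rng.choice(256, size=n_fragments, p=target)
    middle = rng.choice(list("ACGT"), size=(n_fragments, 4))
    pieces = []
    bed_lines = []
    for i in range(n_fragments):
        start = i * _FRAG_LEN
        seq = (
            MOTIFS[watson_idx[i]]
            + "".join(middle[i])
            + revcomp(MOTIFS[crick_idx[i]])
        )
        pieces.append(seq)
        bed_lines.append(f"{chrom}\t{start}\t{start + _FRAG_LEN}\n")
    reference = "".join(pieces)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / "reference.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for j in range(0, len(reference), 60):
            fh.write(reference[j : j + 60] + "\n")
    bed_path = out_dir / "fragments.bed"
    with open(bed_path, "w") as fh:
        fh.writelines(bed_lines)
    return fasta_path, bed_path


def make_founder_fixture(seed: int = 0) -> FounderMatrix:
    """A synthetic stand-in for the six founder end-motif profiles.

    Columns are independent draws from a Dirichlet over the 256 motifs
    (each sums to 1, full column rank 6); it mimics only the shape of a
    founder matrix, not the published nuclease signatures.
    """
    rng = np.random.RandomState(seed)
    cols = rng.dirichlet(np.full(256, 0.5), size=6).T
    return FounderMatrix(values=cols)
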