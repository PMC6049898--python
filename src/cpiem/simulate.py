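"""Synthetic ChIP-seq experiments with known cooperative-binding labels.

The generator realizes the statistical structure the mixture model assumes:
each doubly bound location is cooperative with probability w, and its
(target, partner) intensity pair is drawn with independent axes from the
component's marginals, the cooperative component being weaker on the target
axis.  Around that core it builds complete artifact plumbing for a knockout
validation experiment — wild-type target replicates, a partner peak file,
knockout replicates in which cooperative target peaks are lost (probability
``p_loss``) or attenuated, a single-contig genome with planted motif sites
under the peak summits, and a tab-separated truth table — so that every
downstream module can be exercised without external data.

Defaults encode the reference simulation conditions used throughout the
test-suite: 4000 pairs, w = 0.4, lognormal marginals with target
log-locations 1.0 (cooperative) vs 2.5 (non-cooperative) at log-sd 0.5, and
partner log-locations 2.0 vs 2.1 at log-sd 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .knockout import COOPERATIVE, INDEPENDENT
from .motifs import PWM
from .pairing import PeakPair, find_overlapping_pairs, make_pair
from .peaks import PeakRecord, write_narrowpeak

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_pwm(background=(0.25, 0.25, 0.25, 0.25)) -> PWM:
    """A strong 8-bp motif (consensus TGACGTCA, ~80% per position).

    Off-consensus counts deliberately differ between letters and positions
    so best-hit scores are effectively continuous; a two-valued score
    alphabet would tie heavily at the control-percentile threshold.
    """
    counts = np.array(
        [
            [6.0, 9.0, 4.0, 81.0],  # T
            [7.0, 3.0, 82.0, 8.0],  # G
            [79.0, 6.0, 10.0, 5.0],  # A
            [8.0, 83.0, 4.0, 5.0],  # C
            [5.0, 9.0, 78.0, 8.0],  # G
            [4.0, 7.0, 6.0, 83.0],  # T
            [9.0, 80.0, 6.0, 5.0],  # C
            [84.0, 4.0, 7.0, 5.0],  # A
        ]
    )
    return PWM.from_counts(counts, background=background)


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic knockout experiment."""

    n_pairs: int = 4000
    weight: float = 0.4
    family: str = "lognormal"
    coop_target: tuple[float, float] = (1.0, 0.5)  # (location, scale)
    coop_partner: tuple[float, float] = (2.0, 0.6)
    noncoop_target: tuple[float, float] = (2.5, 0.5)
    noncoop_partner: tuple[float, float] = (2.1, 0.6)
    p_loss: float = 0.8
    attenuation: float = 0.5
    replicate_log_noise: float = 0.1
    n_wt_replicates: int = 2
    n_ko_replicates: int = 2
    genome_length: int = 5_000_000
    mean_peak_length: int = 200
    peak_length_sd: float = 20.0
    min_peak_length: int = 50
    motif_rate: float = 0.9
    pwm: PWM | None = None
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError("weight must lie in [0, 1]")
        if not (0.0 <= self.p_loss <= 1.0):
            raise ValueError("p_loss must lie in [0, 1]")
        if not (0.0 < self.attenuation <= 1.0):
            raise ValueError("attenuation must lie in (0, 1]")
        if not (0.0 <= self.motif_rate <= 1.0):
            raise ValueError("motif_rate must lie in [0, 1]")
        for name in ("coop_target", "coop_partner", "noncoop_target", "noncoop_partner"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"{name} scale must be positive")
        if self.coop_target[0] >= self.noncoop_target[0]:
            raise ValueError(
                "cooperative target location must be below the "
                "non-cooperative one"
            )
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be positive")


@dataclass
class SimulatedExperiment:
    """In-memory result of :func:`simulate_experiment`."""

    wt_target: list[list[PeakRecord]]  # replicates
    partner: list[PeakRecord]
    ko_target: list[list[PeakRecord]]  # replicates
    genome: dict[str, str]
    truth: pd.DataFrame
    pwm: PWM
    config: SimulationConfig = field(repr=False)

    def pairs(self) -> list[PeakPair]:
        """Overlapping pairs of the first wild-type replicate vs partner."""
        return find_overlapping_pairs(self.wt_target[0], self.partner)


def _draw_marginal(rng, family, loc, scale, n):
    if family == "lognormal":
        return np.exp(rng.normal(loc, scale, size=n))
    if family == "gaussian":
        return rng.normal(loc, scale, size=n)
    if family == "gamma":
        return rng.gamma(loc, scale, size=n)
    raise ValueError(f"unknown family {family!r}")


def simulate_intensity_pairs(
    config: SimulationConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw labelled intensity pairs from the two-component model.

    Returns ``(xy, labels)`` where ``xy`` has shape (n_pairs, 2) and
    ``labels`` is True for cooperative draws.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_pairs
    coop = rng.random(n) < config.weight
    xy = np.empty((n, 2))
    for is_coop, tpar, ppar in (
        (True, config.coop_target, config.coop_partner),
        (False, config.noncoop_target, config.noncoop_partner),
    ):
        m = coop == is_coop
        k = int(m.sum())
        xy[m, 0] = _draw_marginal(rng, config.family, *tpar, k)
        xy[m, 1] = _draw_marginal(rng, config.family, *ppar, k)
    return xy, coop


def _random_genome(rng, length: int, background) -> str:
    codes = rng.choice(4, size=length, p=np.asarray(background, float))
    return _LETTERS[codes].tobytes().decode()


def simulate_experiment(
    config: SimulationConfig, seed: int | None = None
) -> SimulatedExperiment:
    """Generate a full synthetic knockout experiment.

    Target peaks are placed one per slot on a jittered grid along a single
    contig, so they never overlap each other; each partner peak is drawn to
    overlap its own target by at least 1 bp and stays inside the slot.
    Summit offsets are uniform within each peak independently of the label,
    so summit distance carries no label information.  In knockout
    replicates, cooperative target peaks are removed with probability
    ``p_loss`` and attenuated by ``attenuation`` otherwise; every observed
    intensity is jittered by the replicate log-noise.  A PWM site sampled
    from the motif model is planted at each target-peak summit at rate
    ``motif_rate``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_pairs
    max_len = int(config.mean_peak_length + 4 * config.peak_length_sd)
    slot = config.genome_length // n
    if slot < 3 * max_len:
        raise ValueError(
            f"genome too small: need >= {3 * max_len * n} bp for "
            f"{n} non-overlapping peak slots, have {config.genome_length}"
        )

    xy, coop = simulate_intensity_pairs(config, seed=int(rng.integers(2**31)))

    def draw_len() -> int:
        return int(
            np.clip(
                rng.normal(config.mean_peak_length, config.peak_length_sd),
                config.min_peak_length,
                max_len,
            )
        )

    chrom = "chrSim"
    noise = config.replicate_log_noise

    targets: list[PeakRecord] = []
    partners: list[PeakRecord] = []
    for i in range(n):
        tlen, plen = draw_len(), draw_len()
        lo = i * slot + max_len
        hi = (i + 1) * slot - max_len - tlen
        ts = int(rng.integers(lo, max(lo + 1, hi)))
        t_summit = int(rng.integers(0, tlen))
        # partner start anywhere that guarantees >= 1 bp overlap
        ps = int(rng.integers(ts - plen + 1, ts + tlen - 1 + 1))
        ps = max(ps, i * slot)  # stay inside the slot
        p_summit = int(rng.integers(0, plen))
        targets.append(
            PeakRecord(
                chrom, ts, ts + tlen, name=f"t{i}", signal=float(xy[i, 0]),
                summit_offset=t_summit,
            )
        )
        partners.append(
            PeakRecord(
                chrom, ps, ps + plen, name=f"p{i}", signal=float(xy[i, 1]),
                summit_offset=p_summit,
            )
        )

    def jitter(v: float) -> float:
        return float(v * np.exp(rng.normal(0.0, noise))) if noise > 0 else v

    wt_reps: list[list[PeakRecord]] = []
    for _ in range(config.n_wt_replicates):
        rep = [
            PeakRecord(
                p.chrom, p.start, p.end, p.name, signal=jitter(p.signal),
                summit_offset=p.summit_offset,
            )
            for p in targets
        ]
        wt_reps.append(rep)

    lost = coop & (rng.random(n) < config.p_loss)
    ko_reps: list[list[PeakRecord]] = []
    for _ in range(config.n_ko_replicates):
        rep = []
        for i, p in enumerate(targets):
            if lost[i]:
                continue
            base = p.signal * (config.attenuation if coop[i] else 1.0)
            rep.append(
                PeakRecord(
                    p.chrom, p.start, p.end, p.name, signal=jitter(base),
                    summit_offset=p.summit_offset,
                )
            )
        ko_reps.append(rep)

    pwm = config.pwm if config.pwm is not None else default_pwm(config.background)
    seq = np.frombuffer(
        _random_genome(rng, config.genome_length, config.background).encode(),
        dtype=np.uint8,
    ).copy()
    planted = rng.random(n) < config.motif_rate
    assert pwm.probs is not None, "simulation PWM must carry probabilities"
    for i, t in enumerate(targets):
        if not planted[i]:
            continue
        site_start = min(t.summit, config.genome_length - pwm.width)
        for j in range(pwm.width):
            letter = rng.choice(4, p=pwm.probs[j])
            seq[site_start + j] = _LETTERS[letter]
    genome = {chrom: seq.tobytes().decode()}

    truth = pd.DataFrame(
        {
            "name": [t.name for t in targets],
            "chrom": chrom,
            "start": [t.start for t in targets],
            "end": [t.end for t in targets],
            "label": np.where(coop, COOPERATIVE, INDEPENDENT),
            "x_true": xy[:, 0],
            "y_true": xy[:, 1],
            "lost_in_ko": lost,
            "motif_planted": planted,
        }
    )
    return SimulatedExperiment(
        wt_target=wt_reps,
        partner=partners,
        ko_target=ko_reps,
        genome=genome,
        truth=truth,
        pwm=pwm,
        config=config,
    )


def write_experiment(exp: SimulatedExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write the experiment as narrowPeak + FASTA + truth TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for r, rep in enumerate(exp.wt_target, 1):
        p = outdir / f"target_wt_rep{r}.narrowPeak"
        write_narrowpeak(rep, p)
        paths[f"target_wt_rep{r}"] = p
    p = outdir / "partner.narrowPeak"
    write_narrowpeak(exp.partner, p)
    paths["partner"] = p
    for r, rep in enumerate(exp.ko_target, 1):
        p = outdir / f"target_ko_rep{r}.narrowPeak"
        write_narrowpeak(rep, p)
        paths[f"target_ko_rep{r}"] = p
    fa = outdir / "genome.fa"
    with open(fa, "w") as fh:
        for name, seq in exp.genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["genome"] = fa
    tt = outdir / "truth.tsv"
    exp.truth.to_csv(tt, sep="\t", index=False)
    paths["truth"] = tt
    pw = outdir / "motif.pwm"
    exp.pwm.write(pw)
    paths["pwm"] = pw
    return paths
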