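"""PWM best-hit scanning and the indirect-binding filter."""

import numpy as np
import pytest

from cpiem import (
    PWM,
    PeakRecord,
    best_hit_score,
    indirect_binding_filter,
    sample_unbound_windows,
)
from cpiem.motifs import nearest_rank_percentile
from cpiem.simulate import _random_genome, default_pwm

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_force_best_hit(seq, pwm):
    """Enumerate every offset on both strands; same tie-breaks as the scanner."""
    idx = {c: i for i, c in enumerate("ACGT")}

    def score_at(s, scores):
        return sum(
            0.0 if c == "N" else scores[i][idx[c]] for i, c in enumerate(s)
        )

    w = pwm.width
    best = None
    for pos in range(len(seq) - w + 1):
        window = seq[pos : pos + w]
        rc = "".join(COMP.get(c, "N") for c in reversed(window))
        for strand, s in (("+", window), ("-", rc)):
            sc = score_at(s, pwm.scores)
            key = (-sc, pos, 0 if strand == "+" else 1)
            if best is None or key < best[0]:
                best = (key, sc, pos, strand)
    return best[1], best[2], best[3]


class TestBestHitScore:
    def test_width_one_palindromic_tie(self):
        pwm = PWM(scores=[[1.0, 0.0, 0.0, -1.0]], background=[0.25] * 4)
        hit = best_hit_score("AT", pwm)
        # forward A at 0 and reverse-strand hit at the T both score 1;
        # tie resolves to position 0, + strand
        assert (hit.score, hit.position, hit.strand) == (1.0, 0, "+")

    def test_width_two_at_motif(self):
        pwm = PWM(
            scores=[[2.0, -1.0, -1.0, -1.0], [-1.0, -1.0, -1.0, 2.0]],
            background=[0.25] * 4,
        )
        hit = best_hit_score("GATC", pwm)
        assert (hit.score, hit.position, hit.strand) == (4.0, 1, "+")

    def test_sequence_shorter_than_width_rejected(self):
        pwm = default_pwm()
        with pytest.raises(ValueError, match="shorter than"):
            best_hit_score("ACGTACG", pwm)

    def test_invalid_letter_rejected(self):
        pwm = PWM(scores=[[1.0, 0.0, 0.0, -1.0]], background=[0.25] * 4)
        with pytest.raises(ValueError, match="invalid letter"):
            best_hit_score("AXT", pwm)

    def test_n_positions_score_neutral(self):
        pwm = PWM(scores=[[1.0, 0.0, 0.0, -1.0]], background=[0.25] * 4)
        assert best_hit_score("NN", pwm).score == 0.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(6)
        pwm = default_pwm()
        for _ in range(25):
            n = int(rng.integers(pwm.width, 100))
            seq = "".join(rng.choice(list("ACGTN"), size=n, p=[0.24] * 4 + [0.04]))
            hit = best_hit_score(seq, pwm)
            score, pos, strand = brute_force_best_hit(seq, pwm)
            assert hit.score == pytest.approx(score, abs=1e-9)
            assert (hit.position, hit.strand) == (pos, strand)


class TestSampleUnboundWindows:
    def _genome_and_peaks(self):
        rng = np.random.default_rng(7)
        genome = {"c1": _random_genome(rng, 50_000, (0.25,) * 4)}
        peaks = [
            PeakRecord("c1", i * 1000, i * 1000 + 400, name=f"p{i}")
            for i in range(25)
        ]
        return genome, peaks

    def test_postconditions(self):
        genome, peaks = self._genome_and_peaks()
        windows = sample_unbound_windows(genome, peaks, 50, 200, seed=8)
        assert len(windows) == 50
        assert all(len(w) == 200 for w in windows)
        assert all("N" not in w for w in windows)

    def test_windows_avoid_peaks(self):
        genome, peaks = self._genome_and_peaks()
        # deterministic check: re-derive the coordinates by masking the genome
        masked = list(genome["c1"])
        for p in peaks:
            for i in range(p.start, p.end):
                masked[i] = "N"
        masked_genome = {"c1": "".join(masked)}
        w1 = sample_unbound_windows(genome, peaks, 50, 200, seed=9)
        w2 = sample_unbound_windows(masked_genome, peaks, 50, 200, seed=9)
        assert w1 == w2  # same draws survive, so none touched a peak

    def test_same_seed_reproducible(self):
        genome, peaks = self._genome_and_peaks()
        assert sample_unbound_windows(
            genome, peaks, 30, 150, seed=10
        ) == sample_unbound_windows(genome, peaks, 30, 150, seed=10)

    def test_fully_covered_genome_rejected(self):
        rng = np.random.default_rng(11)
        genome = {"c1": _random_genome(rng, 10_000, (0.25,) * 4)}
        peaks = [PeakRecord("c1", 0, 10_000)]
        with pytest.raises(ValueError, match="insufficient unbound space"):
            sample_unbound_windows(genome, peaks, 10, 200, seed=12)


class TestIndirectBindingFilter:
    def test_nearest_rank_threshold_and_strict_comparison(self):
        controls = list(range(1, 11))  # 1..10 -> T = 9
        assert nearest_rank_percentile(controls, 90) == 9.0
        pwm = PWM(scores=[[1.0, 0.0, 0.0, -1.0]], background=[0.25] * 4)
        # single-letter peaks: score 1 ("A") is retained vs T=0.5 control set
        genome = {"c1": "AC"}
        peaks = [
            PeakRecord("c1", 0, 1, name="hi"),  # "A" scores 1
            PeakRecord("c1", 1, 2, name="lo"),  # "C" scores 0 fwd, 0 rev
        ]
        retained, flagged, t = indirect_binding_filter(
            peaks, genome, pwm, control_scores=[0.5] * 10
        )
        assert t == 0.5
        assert [p.name for p in retained] == ["hi"]
        assert [p.name for p in flagged] == ["lo"]

    def _background_setup(self, seed):
        rng = np.random.default_rng(seed)
        genome = {"c1": _random_genome(rng, 300_000, (0.25,) * 4)}
        peaks = [
            PeakRecord("c1", i * 400, i * 400 + 200, name=f"p{i}")
            for i in range(300)
        ]
        pwm = default_pwm()
        controls = sample_unbound_windows(genome, peaks, 1000, 200, seed=seed)
        scores = [best_hit_score(s, pwm).score for s in controls]
        return peaks, genome, pwm, scores

    def test_filter_idempotent(self):
        peaks, genome, pwm, scores = self._background_setup(13)
        retained, _, t = indirect_binding_filter(peaks, genome, pwm, scores)
        retained2, flagged2, _ = indirect_binding_filter(
            retained, genome, pwm, scores
        )
        assert flagged2 == [] and retained2 == retained

    def test_raising_percentile_shrinks_retained_set(self):
        peaks, genome, pwm, scores = self._background_setup(14)
        sizes = []
        for pct in (50, 75, 90, 99):
            retained, _, _ = indirect_binding_filter(
                peaks, genome, pwm, scores, percentile=pct
            )
            sizes.append(len(retained))
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            indirect_binding_filter([], {}, default_pwm(), control_scores=[])

    def test_unscannable_peak_flagged_with_warning(self):
        pwm = default_pwm()
        genome = {"c1": "N" * 100}
        peaks = [PeakRecord("c1", 0, 100, name="allN")]
        with pytest.warns(UserWarning, match="not .*scannable|scannable"):
            retained, flagged, _ = indirect_binding_filter(
                peaks, genome, pwm, control_scores=[1.0]
            )
        assert retained == [] and [p.name for p in flagged] == ["allN"]
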