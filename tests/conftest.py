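import numpy as np
import pytest

from orthoprofiler.alignment import GapPenalties, SubstitutionMatrix
from orthoprofiler.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def blosum62():
    return SubstitutionMatrix.load("BLOSUM62")


@pytest.fixture(scope="session")
def emboss_gaps():
    return GapPenalties(open=10.0, extend=0.5, penalize_end_gaps=False)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic study (seed 42),
    shared by the planted-recovery, planted-enrichment and artifact tests."""
    out = tmp_path_factory.mktemp("pipeline") / "run"
    return run_pipeline(PipelineConfig(out_dir=str(out), seed=42))


# ---------------------------------------------------------------------------
# brute-force oracles, kept independent of the implementation paths they check


def enumerate_global_alignments(a: str, b: str):
    """Yield every monotone global alignment of a and b as column lists."""
    def rec(i, j):
        if i == len(a) and j == len(b):
            yield []
            return
        if i < len(a) and j < len(b):
            for rest in rec(i + 1, j + 1):
                yield [(a[i], b[j])] + rest
        if i < len(a):
            for rest in rec(i + 1, j):
                yield [(a[i], "-")] + rest
        if j < len(b):
            for rest in rec(i, j + 1):
                yield [("-", b[j])] + rest
    yield from rec(0, 0)


def score_alignment_columns(cols, matrix, gaps):
    """Score an explicit alignment: affine gap runs (terminal runs free
    unless penalize_end_gaps) plus substitution scores."""
    s = 0.0
    for seq_idx in (0, 1):
        runs = []
        run = start = 0
        for k, col in enumerate(cols):
            if col[seq_idx] == "-":
                if run == 0:
                    start = k
                run += 1
            else:
                if run:
                    runs.append((start, run))
                run = 0
        if run:
            runs.append((start, run))
        for start, length in runs:
            terminal = start == 0 or start + length == len(cols)
            if terminal and not gaps.penalize_end_gaps:
                continue
            s -= gaps.open + length * gaps.extend
    for x, y in cols:
        if x != "-" and y != "-":
            s += matrix.score(x, y)
    return s


def brute_force_best_score(a, b, matrix, gaps):
    return max(score_alignment_columns(cols, matrix, gaps)
               for cols in enumerate_global_alignments(a, b))


def random_alignment_instance(rng, alphabet="ABCD", max_len=6):
    """A random small alignment problem: symmetric integer matrix, random
    affine costs (both end-gap modes), random short sequences."""
    n = len(alphabet)
    scores = rng.integers(-4, 6, size=(n, n)).astype(float)
    scores = (scores + scores.T) / 2
    matrix = SubstitutionMatrix(alphabet, scores)
    gaps = GapPenalties(
        open=float(rng.choice([0.0, 1.0, 2.5, 5.0, 10.0])),
        extend=float(rng.choice([0.0, 0.5, 1.0, 2.0])),
        penalize_end_gaps=bool(rng.random() < 0.5),
    )
    a = "".join(rng.choice(list(alphabet), size=rng.integers(1, max_len + 1)))
    b = "".join(rng.choice(list(alphabet), size=rng.integers(1, max_len + 1)))
    return a, b, matrix, gaps


def rescan_complete_linkage(d: np.ndarray):
    """Naive complete-linkage oracle: at every step re-scan the ORIGINAL
    leaf-leaf distance matrix for the max between cluster members.
    Returns merges as (members_left, members_right, height) with the same
    lowest-index-first tie rule the implementation promises."""
    n = len(d)
    clusters = {i: frozenset([i]) for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        ids = sorted(clusters)
        for ai, i in enumerate(ids):
            for j in ids[ai + 1:]:
                h = max(d[x, y] for x in clusters[i] for y in clusters[j])
                if h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        merges.append((clusters[i], clusters[j], h))
        clusters[next_id] = clusters[i] | clusters[j]
        del clusters[i], clusters[j]
        next_id += 1
    return merges
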