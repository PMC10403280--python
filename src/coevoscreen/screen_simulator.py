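"""Selection-round simulator for paired display screens.

Emulates the statistical structure of a library-on-library yeast display
screen: a latent pairwise affinity landscape assigns every realizable
variant pair a binding affinity (pK_D); round-to-round survival (retention)
is a clipped linear function of pK_D, mirroring the semilog-linear
cleavage-capture readout of the platform; each round resamples the cell
pool in proportion to frequency x retention and sequencing draws counts
multinomially at a configured depth.

Clones are fixed genotypes: selection reweights frequencies, it does not
mutate sequences between rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from coevoscreen.library_design import LibraryDesign, chain_functional_diversity
from coevoscreen.residues import factor_matrix


@dataclass
class PairCountTable:
    """One selection round's paired-sequence read counts.

    The universal exchange format between pipeline stages. ``df`` holds
    columns ``seq_a, seq_b, count`` with unique (seq_a, seq_b) rows and
    counts >= 1.
    """

    round_label: str
    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"seq_a", "seq_b", "count"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"count table needs columns {sorted(required)}")
        if self.df.duplicated(["seq_a", "seq_b"]).any():
            raise ValueError("duplicate (seq_a, seq_b) rows in count table")
        if (self.df["count"] < 1).any():
            raise ValueError("counts must be >= 1")

    @property
    def total(self) -> int:
        return int(self.df["count"].sum())


def write_tables(tables: Sequence[PairCountTable], path: str | Path) -> None:
    """Write rounds to a single TSV `round seq_a seq_b count`; metadata
    (seed etc.) goes into `# key=value` header comments."""
    meta: dict = {}
    for t in tables:
        meta.update(t.meta)
    frames = []
    for t in tables:
        frame = t.df[["seq_a", "seq_b", "count"]].copy()
        frame.insert(0, "round", t.round_label)
        frames.append(frame)
    with open(path, "w") as fh:
        for k in sorted(meta):
            fh.write(f"# {k}={meta[k]}\n")
        pd.concat(frames, ignore_index=True).to_csv(fh, sep="\t", index=False)


def read_tables(path: str | Path) -> list[PairCountTable]:
    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", dtype={"round": str, "seq_a": str, "seq_b": str})
    out = []
    for label, sub in df.groupby("round", sort=False):
        out.append(
            PairCountTable(str(label), sub.drop(columns="round").reset_index(drop=True),
                           dict(meta))
        )
    return out


@dataclass
class GroundTruthLandscape:
    """Latent affinity landscape over the paired variable regions.

    pK_D(a, b) = pkd0 + scale * (sum_i h_A[i][a_i] + sum_j h_B[j][b_j]
                                 + sum_{(i,j) planted} eps[i,j][a_i, b_j])

    ``alphabets_A/B`` fix the amino-acid index for each position; screens
    over restricted sub-alphabets of the same landscape remain valid, which
    is how alphabet-transfer experiments share one ground truth.
    Energies are dimensionless; ``scale`` converts them to pK_D units.
    """

    alphabets_A: list[str]
    alphabets_B: list[str]
    h_A: list[np.ndarray]
    h_B: list[np.ndarray]
    eps: dict[tuple[int, int], np.ndarray]
    pkd0: float = 7.0
    scale: float = 1.0
    planted_pairs: list[tuple[int, int]] = field(default_factory=list)
    seed: int | None = None

    def _index(self, alphabet: str, aa: str, where: str) -> int:
        idx = alphabet.find(aa)
        if idx < 0:
            raise ValueError(f"amino acid {aa!r} not in landscape alphabet at {where}")
        return idx

    def pkd(self, seq_A: str, seq_B: str) -> float:
        if len(seq_A) != len(self.alphabets_A) or len(seq_B) != len(self.alphabets_B):
            raise ValueError("sequence lengths do not match landscape positions")
        e = 0.0
        ia = [self._index(al, aa, f"A{i+1}") for i, (al, aa) in
              enumerate(zip(self.alphabets_A, seq_A))]
        ib = [self._index(al, aa, f"B{j+1}") for j, (al, aa) in
              enumerate(zip(self.alphabets_B, seq_B))]
        for i, k in enumerate(ia):
            e += self.h_A[i][k]
        for j, k in enumerate(ib):
            e += self.h_B[j][k]
        for (i, j), mat in self.eps.items():
            e += mat[ia[i - 1], ib[j - 1]]
        return self.pkd0 + self.scale * e


@dataclass
class SelectionConfig:
    """Screen settings: rounds, pool sizes, depth, retention map, seed.

    Retention is clip_[0,1](m * (pK_D - p0)); the defaults m=0.25, p0=6 map
    pK_D 6 -> 0 and 10 -> 1, spanning the platform's uM-to-nM range.
    """

    n_rounds: int = 5
    naive_diversity: int = 5000
    cells_per_round: int = 50_000
    sequencing_depth: int = 100_000
    m: float = 0.25
    p0: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.naive_diversity, self.cells_per_round, self.sequencing_depth) <= 0:
            raise ValueError("pool sizes and depth must be positive")
        if self.n_rounds < 0:
            raise ValueError("n_rounds must be >= 0")


def build_landscape(
    design: LibraryDesign,
    planted_spec: dict[tuple[int, int], float] | None = None,
    seed: int = 0,
    h_sd: float = 0.5,
    pkd0: float = 7.0,
    scale: float = 1.0,
    smoothness: float = 0.8,
    alphabets_A: Sequence[str] | None = None,
    alphabets_B: Sequence[str] | None = None,
) -> GroundTruthLandscape:
    """Draw a landscape over the design's alphabets with planted couplings.

    Single-site propensities are drawn as a random linear function of the
    residues' physicochemical factor scores plus independent roughness;
    ``smoothness`` is the fraction of the per-position variance carried by
    the factor term. Binding energetics of natural interfaces vary
    smoothly with residue chemistry (hydrophobicity, volume, charge), and
    this structure is what lets an embedding-based model generalize to
    amino acids absent from a training screen; smoothness 0 gives a fully
    idiosyncratic landscape instead.

    ``planted_spec`` maps 1-based (A-position, B-position) variable-region
    index pairs to coupling magnitudes. Each planted pair gets a
    "matched partner" pattern: eps[a, b] = magnitude when b is a's matched
    partner (the most compatible residue under a fixed random bilinear
    form in factor space), 0 otherwise — so matched and mismatched pairs
    at that position differ in pK_D by exactly magnitude * scale, and
    chemically similar residues share partners.

    ``alphabets_A/B`` may override the design's per-position alphabets with
    supersets, so that screens over restricted sub-alphabet designs and
    expanded-alphabet designs can share one ground-truth landscape.
    """
    planted_spec = dict(planted_spec or {})
    rng = np.random.default_rng(seed)
    alph_A = [str(a) for a in alphabets_A] if alphabets_A else list(design.alphabets_A)
    alph_B = [str(a) for a in alphabets_B] if alphabets_B else list(design.alphabets_B)
    for given, overriding, chain in (
        (design.alphabets_A, alph_A, "A"), (design.alphabets_B, alph_B, "B")
    ):
        if len(given) != len(overriding):
            raise ValueError(f"alphabet override length mismatch on chain {chain}")
        for p, (g, o) in enumerate(zip(given, overriding)):
            if not set(g) <= set(o):
                raise ValueError(
                    f"override alphabet at {chain}{p + 1} must contain the design's"
                )
    for (i, j) in planted_spec:
        if not (1 <= i <= len(alph_A)) or not (1 <= j <= len(alph_B)):
            raise ValueError(f"planted position pair {(i, j)} outside design")
    if not 0.0 <= smoothness <= 1.0:
        raise ValueError("smoothness must be in [0, 1]")

    def draw_h(alphabet: str) -> np.ndarray:
        phi = factor_matrix(alphabet)
        smooth = phi @ rng.normal(size=phi.shape[1])
        sd = smooth.std()
        smooth = smooth / sd if sd > 0 else smooth
        rough = rng.normal(size=len(alphabet))
        return h_sd * (
            np.sqrt(smoothness) * smooth + np.sqrt(1.0 - smoothness) * rough
        )

    h_A = [draw_h(a) for a in alph_A]
    h_B = [draw_h(a) for a in alph_B]
    eps: dict[tuple[int, int], np.ndarray] = {}
    for (i, j), mag in sorted(planted_spec.items()):
        pa, pb = alph_A[i - 1], alph_B[j - 1]
        # partner = most compatible residue under a fixed bilinear form in
        # factor space, so chemically similar residues share partners
        compat = factor_matrix(pa) @ rng.normal(size=(5, 5)) @ factor_matrix(pb).T
        mat = np.zeros((len(pa), len(pb)))
        mat[np.arange(len(pa)), compat.argmax(axis=1)] = mag
        eps[(i, j)] = mat
    return GroundTruthLandscape(
        alphabets_A=alph_A, alphabets_B=alph_B, h_A=h_A, h_B=h_B, eps=eps,
        pkd0=pkd0, scale=scale, planted_pairs=sorted(planted_spec), seed=seed,
    )


def binding_and_retention(
    landscape: GroundTruthLandscape,
    seq_A: str,
    seq_B: str,
    config: SelectionConfig,
) -> tuple[float, float]:
    """(pK_D, retention probability) for one variant pair."""
    pkd = landscape.pkd(seq_A, seq_B)
    retention = float(np.clip(config.m * (pkd - config.p0), 0.0, 1.0))
    return pkd, retention


def ground_truth_labels(
    landscape: GroundTruthLandscape,
    pairs: Sequence[tuple[str, str]],
    pkd_threshold: float,
) -> np.ndarray:
    """Binary labels: 1 iff pK_D >= threshold."""
    if not np.isfinite(pkd_threshold):
        raise ValueError("pkd_threshold must be finite")
    return np.array(
        [1 if landscape.pkd(a, b) >= pkd_threshold else 0 for a, b in pairs],
        dtype=int,
    )


# ---- vectorized internals -----------------------------------------------


def _decode(codes: np.ndarray, alphabets: list[str]) -> list[str]:
    """Integer position codes (n x L) -> list of variable-region strings."""
    cols = [np.array(list(a)) for a in alphabets]
    chars = np.stack([cols[j][codes[:, j]] for j in range(len(alphabets))], axis=1)
    return ["".join(row) for row in chars]


def _sample_pair_codes(
    rng: np.random.Generator, sizes_A: list[int], sizes_B: list[int], n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n distinct (variant_A, variant_B) index tuples uniformly."""
    radix = np.array(sizes_A + sizes_B, dtype=np.int64)
    space = int(np.prod(radix, dtype=np.float64))
    if n > space:
        raise ValueError(f"naive_diversity {n} exceeds realizable pair space {space}")
    if space <= 4 * n or space <= 1_000_000:
        flat = rng.choice(space, size=n, replace=False)
    else:
        seen: set[int] = set()
        while len(seen) < n:
            draw = rng.integers(0, space, size=n - len(seen))
            seen.update(int(x) for x in draw)
        flat = np.fromiter(sorted(seen), dtype=np.int64)
        flat = rng.permutation(flat)
    codes = np.empty((n, len(radix)), dtype=np.int64)
    rem = np.asarray(flat, dtype=np.int64)
    for j in range(len(radix) - 1, -1, -1):
        codes[:, j] = rem % radix[j]
        rem = rem // radix[j]
    la = len(sizes_A)
    return codes[:, :la], codes[:, la:]


def _pool_pkd(
    landscape: GroundTruthLandscape,
    codes_A: np.ndarray,
    codes_B: np.ndarray,
    alph_A: list[str],
    alph_B: list[str],
) -> np.ndarray:
    """Vectorized pK_D for coded pools (codes index the *screen* alphabets,
    which may be sub-alphabets of the landscape's)."""
    maps_A = [
        np.array([landscape._index(la, aa, f"A{i+1}") for aa in sa])
        for i, (la, sa) in enumerate(zip(landscape.alphabets_A, alph_A))
    ]
    maps_B = [
        np.array([landscape._index(lb, aa, f"B{j+1}") for aa in sb])
        for j, (lb, sb) in enumerate(zip(landscape.alphabets_B, alph_B))
    ]
    land_A = np.stack([maps_A[i][codes_A[:, i]] for i in range(codes_A.shape[1])], axis=1)
    land_B = np.stack([maps_B[j][codes_B[:, j]] for j in range(codes_B.shape[1])], axis=1)
    e = np.zeros(len(codes_A))
    for i in range(land_A.shape[1]):
        e += landscape.h_A[i][land_A[:, i]]
    for j in range(land_B.shape[1]):
        e += landscape.h_B[j][land_B[:, j]]
    for (i, j), mat in landscape.eps.items():
        e += mat[land_A[:, i - 1], land_B[:, j - 1]]
    return landscape.pkd0 + landscape.scale * e


def _counts_table(
    label: str,
    counts: np.ndarray,
    seqs_A: list[str],
    seqs_B: list[str],
    meta: dict,
) -> PairCountTable:
    keep = counts > 0
    df = pd.DataFrame(
        {
            "seq_a": [seqs_A[i] for i in np.nonzero(keep)[0]],
            "seq_b": [seqs_B[i] for i in np.nonzero(keep)[0]],
            "count": counts[keep].astype(int),
        }
    )
    df = df.sort_values(["seq_a", "seq_b"], ignore_index=True)
    return PairCountTable(label, df, dict(meta))


def _integer_allocate(freq: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder allocation of `total` among bins ∝ freq."""
    raw = freq / freq.sum() * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def simulate_screen(
    design: LibraryDesign,
    landscape: GroundTruthLandscape,
    config: SelectionConfig,
    noise: Literal["stochastic", "off"] = "stochastic",
) -> list[PairCountTable]:
    """Run a screen: naive table plus one table per selection round.

    The naive pool is a uniform without-replacement sample of
    ``naive_diversity`` pairs from the realizable pair space. Each round
    resamples ``cells_per_round`` cells with probability proportional to
    current frequency x retention, then sequencing draws
    ``sequencing_depth`` reads multinomially. With ``noise="off"`` the
    deterministic frequency recursion f <- f*r / sum(f*r) is applied and
    counts are largest-remainder integerizations (for oracle tests).
    """
    rng = np.random.default_rng(config.seed)
    sizes_A = [len(a) for a in design.alphabets_A]
    sizes_B = [len(a) for a in design.alphabets_B]
    codes_A, codes_B = _sample_pair_codes(rng, sizes_A, sizes_B, config.naive_diversity)
    seqs_A = _decode(codes_A, design.alphabets_A)
    seqs_B = _decode(codes_B, design.alphabets_B)
    pkd = _pool_pkd(landscape, codes_A, codes_B, design.alphabets_A, design.alphabets_B)
    retention = np.clip(config.m * (pkd - config.p0), 0.0, 1.0)

    meta = {"seed": config.seed, "design": design.name, "noise": noise}
    freq = np.full(config.naive_diversity, 1.0 / config.naive_diversity)
    tables = []
    if noise == "stochastic":
        counts0 = rng.multinomial(config.sequencing_depth, freq)
    else:
        counts0 = _integer_allocate(freq, config.sequencing_depth)
    tables.append(_counts_table("naive", counts0, seqs_A, seqs_B, meta))

    for r in range(1, config.n_rounds + 1):
        w = freq * retention
        total = w.sum()
        if total <= 0:
            raise RuntimeError(f"round {r}: no pair has nonzero retention")
        w = w / total
        if noise == "stochastic":
            cells = rng.multinomial(config.cells_per_round, w)
            freq = cells / config.cells_per_round
            if freq.sum() == 0:
                raise RuntimeError(f"round {r}: selection emptied the pool")
            counts = rng.multinomial(config.sequencing_depth, freq / freq.sum())
        else:
            freq = w
            counts = _integer_allocate(freq, config.sequencing_depth)
        tables.append(_counts_table(f"round{r}", counts, seqs_A, seqs_B, meta))
    return tables
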