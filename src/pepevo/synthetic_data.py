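"""Ground-truth generators: planted Potts models, families, Ki landscapes.

Every pipeline stage gets an oracle without external data: a *planted* Potts
model with known conserved positions and coupled pairs provides the
recovery benchmark for the pseudolikelihood fit; exact enumeration of small
state spaces provides the Boltzmann oracle for the Metropolis sampler; and a
log-scale affinity landscape aligned with the planted model provides labels
for the regression and leave-out stages. The alignment between landscape and
model is deliberate: experimentally, binder families come out of
display-based selection, so sequence statistics and affinity are entangled,
and the tests should reflect that coupling.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .mc_sampler import SamplerConfig, sample_sequences
from .plmdca import PottsModel
from .seq_core import (MSA, AffinityRecord, Alphabet, Scaffold, CANONICAL_AA)

logger = logging.getLogger("pepevo")

ENUMERATION_CAP = 10 ** 6


@dataclass
class PlantedModel:
    """A Potts model with known strong fields and couplings.

    ``conserved`` maps 1-based variable positions to the boosted residue;
    ``planted_pairs`` lists 1-based position pairs whose single boosted
    (a, b) coupling entry exceeds the background scale by a stated factor.
    """

    potts: PottsModel
    planted_pairs: list[tuple[int, int]]
    planted_entries: dict[tuple[int, int], tuple[str, str]]
    conserved: dict[int, str]
    seed: int


@dataclass
class SyntheticLandscape:
    """Deterministic log10-Ki landscape; noise enters only at observation.

    log10 Ki(nM) = intercept + sum_i additive[i, sigma_i]
                 + sum planted pair effects, with lognormal measurement
    noise of ``noise_sd`` log10 units added by :func:`observe_ki`.
    """

    additive: np.ndarray                      # (L, q) log10 contributions
    pair_effects: dict[tuple[int, int, str, str], float]  # 1-based positions
    intercept: float                          # log10 nM
    noise_sd: float
    alphabet: Alphabet
    scaffold: Scaffold
    seed: int = 0

    def true_log10_ki_nm(self, sequence: str) -> float:
        sigma = self.alphabet.encode(sequence)
        y = self.intercept + float(self.additive[np.arange(len(sigma)), sigma].sum())
        for (i, j, a, b), v in self.pair_effects.items():
            if sequence[i - 1] == a and sequence[j - 1] == b:
                y += v
        return y

    def true_ki_molar(self, sequence: str) -> float:
        return 10.0 ** self.true_log10_ki_nm(sequence) * 1e-9


def _reduced_alphabet(q: int) -> Alphabet:
    if not 2 <= q <= 20:
        raise ValueError("alphabet size must be in [2, 20]")
    return Alphabet(CANONICAL_AA[:q])


def make_planted_model(L: int, q: int, n_conserved: int, n_pairs: int,
                       field_scale: float, coupling_scale: float, seed: int,
                       scaffold: Scaffold | None = None,
                       background_field_sd: float = 0.1,
                       background_coupling_sd: float = 0.05) -> PlantedModel:
    """Draw a background Potts model and plant strong fields/couplings.

    Background entries are small-variance Gaussians; each conserved position
    gets ``field_scale`` added to one residue's field, and each planted pair
    gets ``coupling_scale`` added to a single (a, b) coupling entry. Conserved
    positions and planted pairs involve variable scaffold positions only.
    """
    alphabet = _reduced_alphabet(q)
    scaffold = scaffold or Scaffold(L=L, fixed={}, name=f"free-{L}")
    if scaffold.L != L:
        raise ValueError("scaffold length disagrees with L")
    rng = np.random.default_rng(seed)
    variable = scaffold.variable_positions
    var_pairs = list(itertools.combinations(variable, 2))
    if n_conserved > len(variable):
        raise ValueError("more conserved positions than variable positions")
    if n_pairs > len(var_pairs):
        raise ValueError("more planted pairs than variable position pairs")

    model = PottsModel.zeros(scaffold, alphabet)
    h = rng.normal(0.0, background_field_sd, size=model.h.shape)
    J = rng.normal(0.0, background_coupling_sd, size=model.J.shape)

    conserved_pos = sorted(rng.choice(variable, size=n_conserved, replace=False))
    conserved: dict[int, str] = {}
    for pos in conserved_pos:
        res = int(rng.integers(q))
        h[pos - 1, res] += field_scale
        conserved[int(pos)] = alphabet.symbols[res]

    pair_idx = rng.choice(len(var_pairs), size=n_pairs, replace=False)
    planted_pairs = sorted(var_pairs[k] for k in pair_idx)
    planted_entries: dict[tuple[int, int], tuple[str, str]] = {}
    for (i, j) in planted_pairs:
        a, b = int(rng.integers(q)), int(rng.integers(q))
        J[model.pair_index(i - 1, j - 1), a, b] += coupling_scale
        planted_entries[(i, j)] = (alphabet.symbols[a], alphabet.symbols[b])

    potts = PottsModel(h=h, J=J, alphabet=alphabet, scaffold=scaffold,
                       meta={"planted": True, "seed": seed,
                             "field_scale": field_scale,
                             "coupling_scale": coupling_scale})
    return PlantedModel(potts=potts, planted_pairs=[tuple(map(int, p)) for p in planted_pairs],
                        planted_entries=planted_entries, conserved=conserved,
                        seed=seed)


def enumerate_distribution(model: PottsModel
                           ) -> tuple[list[str], np.ndarray]:
    """Exact Boltzmann table P(sigma) = exp(S)/Z over conformant sequences.

    Enumerates the scaffold's variable positions (fixed positions clamped),
    i.e. all q^L sequences for a free scaffold. Refuses state spaces beyond
    10^6, which keeps the oracle desk-scale.
    """
    q = model.q
    n_var = model.scaffold.n_variable
    size = q ** n_var
    if size > ENUMERATION_CAP:
        raise ValueError(f"state space {q}^{n_var} = {size} exceeds "
                         f"enumeration cap {ENUMERATION_CAP}")
    variable = [p - 1 for p in model.scaffold.variable_positions]
    template = np.zeros(model.L, dtype=np.int64)
    for pos, sym in model.scaffold.fixed.items():
        template[pos - 1] = model.alphabet.index(sym)
    combos = np.array(np.meshgrid(*[np.arange(q)] * n_var,
                                  indexing="ij")).reshape(n_var, -1).T
    matrix = np.tile(template, (size, 1))
    matrix[:, variable] = combos
    scores = model.score_many(matrix)
    logZ = scores.max() + np.log(np.exp(scores - scores.max()).sum())
    probs = np.exp(scores - logZ)
    sequences = [model.alphabet.decode(row) for row in matrix]
    return sequences, probs


def sample_family(model: PottsModel, n: int, seed: int,
                  method: str = "long_mc", unique: bool = False,
                  spacing: int | None = None, id_prefix: str = "S") -> MSA:
    """Draw a family of n sequences from the Potts distribution.

    ``exact_enumeration`` draws i.i.d. from the exact table (enumerable
    spaces only); ``long_mc`` records well-spaced states of one long
    Metropolis chain (default spacing 20*L proposals after a 200*L burn-in),
    which is the route for realistically sized scaffolds. ``unique=True``
    oversamples until n distinct sequences are collected.
    """
    rng = np.random.default_rng(seed)
    if method == "exact_enumeration":
        sequences, probs = enumerate_distribution(model)
        if unique:
            chosen: list[str] = []
            seen = set()
            while len(chosen) < n:
                draw = rng.choice(len(sequences), size=n, p=probs)
                for k in draw:
                    if sequences[k] not in seen:
                        seen.add(sequences[k])
                        chosen.append(sequences[k])
                        if len(chosen) == n:
                            break
        else:
            idx = rng.choice(len(sequences), size=n, p=probs)
            chosen = [sequences[k] for k in idx]
    elif method == "long_mc":
        L = model.L
        spacing = spacing or 20 * L
        burn = 200 * L
        factor = 1
        while True:
            steps = burn + spacing * n * factor
            config = SamplerConfig(n_chains=1, steps=steps, burn_in=burn,
                                   thinning=spacing, temperature=1.0,
                                   seed=int(rng.integers(2 ** 31)),
                                   init="random_scaffold_conformant")
            pool = sample_sequences(model, model.scaffold, config)
            drawn: list[str] = []
            for s, c in zip(pool.samples, pool.counts):
                drawn.extend([s.sequence] * (1 if unique else c))
            if unique:
                drawn = [s.sequence for s in pool.samples]
            if len(drawn) >= n:
                chosen = drawn[:n]
                break
            factor *= 2  # rare: highly peaked model, keep the chain running
            if factor > 64:
                raise RuntimeError("could not collect enough distinct sequences")
    else:
        raise ValueError(f"unknown sampling method {method!r}")
    ids = [f"{id_prefix}{k + 1:04d}" for k in range(n)]
    return MSA.from_sequences(ids, chosen, model.scaffold, model.alphabet)


def make_landscape(scaffold: Scaffold, sparsity: float = 1.0,
                   effect_sd: float = 0.25, noise_sd: float = 0.15,
                   seed: int = 0, alphabet: Alphabet | None = None,
                   align_with: PlantedModel | None = None,
                   align_strength: float = 0.5,
                   n_random_pairs: int = 2,
                   target_median_nm: float = 100.0) -> SyntheticLandscape:
    """Draw a log10-Ki landscape over scaffold-conformant sequences.

    Additive per-(position, residue) effects are N(0, effect_sd), kept with
    probability ``sparsity``; a few sparse pair effects are drawn as well.
    With ``align_with``, favorable (negative, i.e. potency-increasing)
    contributions of ``align_strength`` are placed on the planted model's
    conserved residues and coupled residue pairs, entangling Potts score and
    affinity the way display selection does. The intercept is calibrated on
    1000 random conformant sequences so the median true Ki is about
    ``target_median_nm``; at the defaults the central 95% of random
    sequences spans >= 250-fold, the scale reported for real families.
    """
    alphabet = alphabet or Alphabet()
    rng = np.random.default_rng(seed)
    L, q = scaffold.L, alphabet.q
    additive = rng.normal(0.0, effect_sd, size=(L, q))
    additive *= rng.random(size=(L, q)) < sparsity
    for pos in scaffold.fixed:
        additive[pos - 1, :] = 0.0  # constant across conformant sequences

    pair_effects: dict[tuple[int, int, str, str], float] = {}
    variable = scaffold.variable_positions
    var_pairs = list(itertools.combinations(variable, 2))
    for _ in range(min(n_random_pairs, len(var_pairs))):
        i, j = var_pairs[rng.integers(len(var_pairs))]
        a = alphabet.symbols[rng.integers(q)]
        b = alphabet.symbols[rng.integers(q)]
        pair_effects[(i, j, a, b)] = float(rng.normal(0.0, effect_sd))

    if align_with is not None:
        for pos, res in align_with.conserved.items():
            additive[pos - 1, alphabet.index(res)] -= align_strength
        for (i, j), (a, b) in align_with.planted_entries.items():
            key = (i, j, a, b)
            pair_effects[key] = pair_effects.get(key, 0.0) - align_strength

    landscape = SyntheticLandscape(additive=additive, pair_effects=pair_effects,
                                   intercept=0.0, noise_sd=noise_sd,
                                   alphabet=alphabet, scaffold=scaffold,
                                   seed=seed)
    calib_rng = np.random.default_rng(seed + 1)
    raw = [landscape.true_log10_ki_nm(
        scaffold.random_conformant(calib_rng, alphabet)) for _ in range(1000)]
    landscape.intercept = float(np.log10(target_median_nm) - np.median(raw))
    return landscape


def observe_ki(landscape: SyntheticLandscape, sequences, seed: int,
               ids=None, family: str = "synthetic") -> list[AffinityRecord]:
    """Noisy Ki observations: lognormal measurement error on the true value."""
    if isinstance(sequences, MSA):
        ids = sequences.ids
        sequences = sequences.sequences()
    sequences = list(sequences)
    ids = ids or [f"{family}{k + 1:04d}" for k in range(len(sequences))]
    rng = np.random.default_rng(seed)
    records = []
    for seq_id, seq in zip(ids, sequences):
        y = landscape.true_log10_ki_nm(seq) + rng.normal(0.0, landscape.noise_sd)
        records.append(AffinityRecord(id=seq_id, sequence=seq,
                                      ki=10.0 ** y * 1e-9, family=family))
    return records


# ---------------------------------------------------------------------------
# standard benchmarks


def standard_planted_benchmark(seed: int = 20240101
                               ) -> tuple[PlantedModel, MSA]:
    """The coupling-recovery benchmark: L=10, q=8, 2 conserved positions,
    5 planted pairs with a coupling boost 10x the background sd, n=2000.

    The background coupling sd (0.2) is set so the boosted entry (2.0)
    clears the estimation-noise floor of pseudolikelihood norms at n=2000:
    with much weaker backgrounds the single planted entry is statistically
    invisible and no correct fitter could rank it.
    """
    planted = make_planted_model(L=10, q=8, n_conserved=2, n_pairs=5,
                                 field_scale=3.0, coupling_scale=2.0,
                                 background_field_sd=0.1,
                                 background_coupling_sd=0.2, seed=seed)
    msa = sample_family(planted.potts, n=2000, seed=seed + 1, method="long_mc")
    return planted, msa


def benchmark_round_config(seed: int = 0):
    """Round configuration used with :func:`benchmark_family`.

    The sampler is sized to the published campaign scale (tens of thousands
    of recorded states, ~10^3-10^4 unique sequences): 100 chains x 3000
    steps, burn-in 500, thinning 5. Everything else is at package defaults.
    """
    from .mc_sampler import SamplerConfig
    from .pipeline import RoundConfig

    return RoundConfig(seed=seed,
                       sampler=SamplerConfig(n_chains=100, steps=3000,
                                             burn_in=500, thinning=5))


def benchmark_scaffold() -> Scaffold:
    """A miniature bicyclic template: alanine start, three pinned cysteines,
    six variable loop positions."""
    return Scaffold(L=10, fixed={1: "A", 2: "C", 6: "C", 10: "C"},
                    name="mini-bicycle")


def benchmark_family(seed: int = 0, n: int = 50
                     ) -> tuple[list[AffinityRecord], Scaffold,
                                PlantedModel, SyntheticLandscape]:
    """The full-pipeline benchmark family: n unique sequences from a strongly
    conserved planted model over the miniature bicyclic scaffold, with Ki
    labels from an aligned landscape.

    Background fields of sd 4.0 concentrate each loop position on a couple
    of residues, so family members sit within ~3 mutations of the consensus
    — the concentration display-selected families show (real campaigns on
    ~50-sequence families produced only hundreds to a few thousand unique
    MC sequences, which bounds the effective design space the family
    occupies). 2 conserved positions and 2 planted pairs carry the
    covariation signal, and the aligned landscape makes high-scoring
    sequences potent on average.
    """
    scaffold = benchmark_scaffold()
    planted = make_planted_model(L=scaffold.L, q=20, n_conserved=2, n_pairs=2,
                                 field_scale=3.0, coupling_scale=2.0,
                                 background_field_sd=4.0,
                                 background_coupling_sd=0.05,
                                 seed=seed, scaffold=scaffold)
    msa = sample_family(planted.potts, n=n, seed=seed + 1, method="long_mc",
                        unique=True)
    landscape = make_landscape(scaffold, effect_sd=0.25, noise_sd=0.15,
                               seed=seed + 2, align_with=planted,
                               align_strength=0.5)
    records = observe_ki(landscape, msa, seed=seed + 3, family="bench")
    return records, scaffold, planted, landscape
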