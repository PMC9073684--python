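"""Synthetic TE families with known selection ground truth.

One family proliferates inside a genome from a single ancestral copy.
Each transposition copies the parent's current coding sequence and adds
Poisson(u*L) point mutations; synonymous changes are neutral for
transposition, and a nonsynonymous change is neutral with probability f,
otherwise it is deleterious and multiplies the element's subsequent
transposition rate by (1 - s). Under *cis* action the gene products of a
copy mobilize that copy only, so an element's own mutation load sets its
offspring number and deleterious variants are held down in frequency;
under *trans* action products are shared, every element transposes at the
population-mean rate, and load is invisible to selection. These are the
two signature regimes: declining vN/vS with variant frequency under cis,
a flat curve at ~1 under trans.

The demography has two epochs. First the family grows from the founder to
``max_elements`` copies, either as a free branching process
(``growth="branching"``: each element spawns Poisson(base_rate *
(1-s)^n_del) copies per generation, population-mean rate under trans) or,
by default, conditioned on the logistic-free trajectory
(``growth="conditioned"``: births per generation follow the deterministic
schedule and parents are drawn multinomially with weights (1-s)^n_del,
i.e. the branching process conditioned on its total). Then, for
``turnover_generations`` generations, copy number is held constant while
a fraction ``loss_rate`` of elements is deleted at random each generation
and replaced by new transpositions from the survivors, again
fitness-weighted. The turnover epoch represents the equilibrium between
transposition and element loss that shapes old TE families; it is what
populates the intermediate and high frequency categories of the variant
spectrum. Set ``turnover_generations=0`` for the pure expansion model.

The alignment emitted at the end contains every element alive at the end,
gap-free, plus the full genealogy (including dead lineages) and a
per-mutation truth table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ._codes import AA_INDEX_BY_CODE, codon_to_code
from .alignment import CodonAlignment
from .codon_sets import builtin_codon_sets

__all__ = [
    "SimParams",
    "SimulationResult",
    "simulate_family",
    "simulate_families",
    "simulate_duplication_noise",
    "to_newick",
]


@dataclass(frozen=True)
class SimParams:
    """Simulator parameters.

    u : per-codon, per-copy-event mutation probability.
    f : fraction of nonsynonymous mutations neutral for transposition.
    s : transposition-rate reduction per deleterious mutation
        (multiplicative, in [0, 1]; s = 1 is a lethal class).
    mode : "cis" (own load sets offspring number) or "trans"
        (population-mean rate for everyone).
    n_generations : cap on expansion-epoch generations.
    base_rate : expected transpositions per load-free element per
        generation during expansion; growth factor is 1 + base_rate.
    max_elements : copy number at which expansion stops; also the final
        alignment size.
    L : codon columns per element (>= 50).
    seed : seed for the single numpy Generator driving all randomness.
    ancestral_sequence : optional tuple of codon strings; by default the
        ancestor is sampled uniformly from the builtin codon-set members,
        making every column scannable.
    growth : "conditioned" (default) or "branching"; see module docstring.
    turnover_generations : length of the constant-size turnover epoch.
    loss_rate : per-element, per-generation deletion probability during
        turnover; deaths are fitness-independent (loss is excision or
        silencing, not transposition).
    """

    u: float = 2e-3
    f: float = 0.15
    s: float = 0.7
    mode: str = "cis"
    n_generations: int = 100
    base_rate: float = 0.5
    max_elements: int = 130
    L: int = 500
    seed: int = 0
    ancestral_sequence: Optional[tuple] = None
    growth: str = "conditioned"
    turnover_generations: int = 80
    loss_rate: float = 0.8

    def __post_init__(self):
        if not 0 <= self.f <= 1:
            raise ValueError("f must be in [0, 1]")
        if not 0 <= self.s <= 1:
            raise ValueError("s must be in [0, 1]")
        if self.u <= 0:
            raise ValueError("u must be positive")
        if self.L < 50:
            raise ValueError("L must be >= 50")
        if self.mode not in ("cis", "trans"):
            raise ValueError("mode must be 'cis' or 'trans'")
        if self.growth not in ("conditioned", "branching"):
            raise ValueError("growth must be 'conditioned' or 'branching'")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        if not 0 <= self.loss_rate < 1:
            raise ValueError("loss_rate must be in [0, 1)")
        if self.turnover_generations < 0:
            raise ValueError("turnover_generations must be >= 0")


@dataclass
class SimulationResult:
    """Alignment + genealogy + mutation truth table of one simulated family.

    ``parents[i]`` is the index of element i's parent (-1 for the root)
    and ``birth_generation[i]`` its birth time; together they define the
    genealogy of every element ever born, dead lineages included.
    ``alive`` lists the indices emitted in the alignment. ``mutations``
    has one row per mutation with its element, 1-based codon column,
    codon position, class, selective status and generation. ``extinct``
    flags a population that never reached 2 elements; ``truncated`` flags
    a branching expansion stopped at the cap mid-generation.
    """

    alignment: Optional[CodonAlignment]
    params: SimParams
    ids: list
    parents: np.ndarray
    birth_generation: np.ndarray
    n_deleterious: np.ndarray
    alive: np.ndarray
    mutations: pd.DataFrame
    extinct: bool = False
    truncated: bool = False
    n_generations_run: int = 0


_MUT_COLUMNS = ["mutation_id", "element_id", "column", "position",
                "class", "status", "generation"]


def _default_ancestor(L: int, rng: np.random.Generator) -> np.ndarray:
    members = sorted(
        {codon_to_code(c) for s in builtin_codon_sets() for c in s.codons}
    )
    return rng.choice(np.array(members, dtype=np.uint8), size=L)


def _fitness_weights(n_del: np.ndarray, s: float) -> np.ndarray:
    """Relative transposition weights (1-s)^load, stabilized by recentering
    on the least-loaded class (soft selection: only relative rates matter)."""
    if s == 0:
        return np.ones(len(n_del))
    rel = n_del - n_del.min()
    return np.power(1.0 - s, rel, dtype=float)


class _Family:
    """Mutable simulation state over all elements ever born.

    Genomes live in a capacity-doubling (n_ever, L) uint8 matrix; births
    are applied one generation at a time so row copies, Poisson draws and
    mutation placement are vectorized.
    """

    def __init__(self, root: np.ndarray, params: SimParams,
                 rng: np.random.Generator):
        self.params = params
        self.rng = rng
        L = params.L
        self._G = np.empty((256, L), dtype=np.uint8)
        self._G[0] = root
        self.n_ever = 1
        self.parents = [-1]
        self.birth_gen = [0]
        self._n_del = np.zeros(256, dtype=np.int64)
        self.alive = np.array([0])
        self._mut_batches: list[dict] = []
        self.n_mutations = 0
        self.mean_mut = params.u * params.L

    @property
    def n_del(self) -> np.ndarray:
        return self._n_del[: self.n_ever]

    def genome(self, idx: int) -> np.ndarray:
        return self._G[idx]

    def _ensure_capacity(self, extra: int) -> None:
        need = self.n_ever + extra
        cap = self._G.shape[0]
        if need > cap:
            while cap < need:
                cap *= 2
            grown = np.empty((cap, self.params.L), dtype=np.uint8)
            grown[: self.n_ever] = self._G[: self.n_ever]
            self._G = grown
            grown_del = np.zeros(cap, dtype=np.int64)
            grown_del[: self.n_ever] = self._n_del[: self.n_ever]
            self._n_del = grown_del

    def spawn_batch(self, parent_idx: np.ndarray, gen: int) -> None:
        """Create one generation's children of the given (global) parents.

        Mutations are drawn and applied vectorized; the rare case of two
        mutations hitting the same (element, codon) within one batch is
        replayed sequentially so later hits see earlier ones.
        """
        b = len(parent_idx)
        if b == 0:
            return
        rng = self.rng
        self._ensure_capacity(b)
        start = self.n_ever
        G = self._G
        G[start:start + b] = G[parent_idx]

        ks = rng.poisson(self.mean_mut, size=b)
        total = int(ks.sum())
        rows = np.repeat(np.arange(start, start + b), ks)
        cols = rng.integers(self.params.L, size=total)
        poss = rng.integers(3, size=total)
        base_steps = rng.integers(3, size=total)
        neutral_draws = rng.random(total)
        load_inc = np.zeros(b, dtype=np.int64)

        if total:
            shifts = 2 * (2 - poss)
            old_codes = G[rows, cols].astype(np.int64)
            # replay duplicated (row, col) targets sequentially below
            flat = rows * np.int64(self.params.L) + cols
            _, first_pos, counts = np.unique(flat, return_index=True,
                                             return_counts=True)
            dup_targets = set(flat[first_pos[counts > 1]].tolist())

            old_bases = (old_codes >> shifts) & 3
            new_bases = base_steps + (base_steps >= old_bases)
            new_codes = old_codes + ((new_bases - old_bases) << shifts)
            if not dup_targets:
                G[rows, cols] = new_codes
            else:
                seq = np.nonzero(np.isin(flat, list(dup_targets)))[0]
                clean = np.nonzero(~np.isin(flat, list(dup_targets)))[0]
                G[rows[clean], cols[clean]] = new_codes[clean]
                for i in seq:
                    code = int(G[rows[i], cols[i]])
                    ob = (code >> shifts[i]) & 3
                    nb = base_steps[i] + (base_steps[i] >= ob)
                    nc = code + ((int(nb) - ob) << int(shifts[i]))
                    G[rows[i], cols[i]] = nc
                    old_codes[i], new_codes[i] = code, nc
            synonymous = (AA_INDEX_BY_CODE[old_codes]
                          == AA_INDEX_BY_CODE[new_codes])
            deleterious = ~synonymous & (neutral_draws >= self.params.f)
            np.add.at(load_inc, rows[deleterious] - start, 1)
            self._mut_batches.append({
                "mutation_id": self.n_mutations + np.arange(total),
                "element": rows,
                "column": cols + 1,
                "position": poss + 1,
                "synonymous": synonymous,
                "deleterious": deleterious,
                "generation": np.full(total, gen),
            })
            self.n_mutations += total

        self.parents.extend(int(p) for p in parent_idx)
        self.birth_gen.extend([gen] * b)
        self._n_del[start:start + b] = self._n_del[parent_idx] + load_inc
        self.alive = np.concatenate([self.alive,
                                     np.arange(start, start + b)])
        self.n_ever += b

    def alive_loads(self) -> np.ndarray:
        return self._n_del[self.alive]

    def pick_parents(self, n_births: int) -> np.ndarray:
        """Global indices of fitness-weighted parents for n_births children."""
        if self.params.mode == "cis" and self.params.s > 0:
            w = _fitness_weights(self.alive_loads(), self.params.s)
            picks = self.rng.choice(len(self.alive), size=n_births,
                                    p=w / w.sum())
        else:
            picks = self.rng.integers(len(self.alive), size=n_births)
        return self.alive[picks]


def simulate_family(params: SimParams) -> SimulationResult:
    """Simulate one TE family; see the module docstring for the model."""
    rng = np.random.default_rng(params.seed)
    if params.ancestral_sequence is not None:
        root = np.array([codon_to_code(c) for c in params.ancestral_sequence],
                        dtype=np.uint8)
        if root.shape[0] != params.L:
            raise ValueError("ancestral_sequence length differs from L")
    else:
        root = _default_ancestor(params.L, rng)

    fam = _Family(root, params, rng)
    truncated = False
    gen = 0

    # -- expansion epoch ---------------------------------------------------
    for gen in range(1, params.n_generations + 1):
        n = len(fam.alive)
        if n >= params.max_elements:
            break
        if params.growth == "conditioned":
            target = min(params.max_elements,
                         max(n + 1, int(np.ceil(n * (1 + params.base_rate)))))
            fam.spawn_batch(fam.pick_parents(target - n), gen)
        else:  # branching
            load = fam.alive_loads()
            if params.mode == "cis":
                rates = params.base_rate * np.power(1.0 - params.s, load,
                                                    dtype=float)
            else:
                rates = np.full(n, params.base_rate *
                                np.power(1.0 - params.s, load,
                                         dtype=float).mean())
            offspring = rng.poisson(rates)
            parents_flat = np.repeat(fam.alive, offspring)
            if n + len(parents_flat) > params.max_elements:
                parents_flat = parents_flat[: params.max_elements - n]
                truncated = True
            fam.spawn_batch(parents_flat, gen)
            if truncated:
                gen += 1
                break

    # -- turnover epoch ----------------------------------------------------
    last_expansion_gen = gen
    for t in range(params.turnover_generations):
        gen = last_expansion_gen + t + 1
        n = len(fam.alive)
        if n < 2:
            break
        n_die = int(rng.binomial(n, params.loss_rate))
        if n_die == 0:
            continue
        if n_die == n:  # keep the family extant: spare one element
            n_die = n - 1
        dead_pos = rng.choice(n, size=n_die, replace=False)
        keep = np.ones(n, dtype=bool)
        keep[dead_pos] = False
        survivors = fam.alive[keep]
        fam.alive = survivors
        fam.spawn_batch(fam.pick_parents(n_die), gen)

    alive = np.sort(fam.alive)
    ids_all = [f"e{i}" for i in range(fam.n_ever)]
    if fam._mut_batches:
        cat = {k: np.concatenate([batch[k] for batch in fam._mut_batches])
               for k in fam._mut_batches[0]}
        mutations = pd.DataFrame({
            "mutation_id": cat["mutation_id"],
            "element_id": pd.Series(cat["element"]).map("e{}".format),
            "column": cat["column"],
            "position": cat["position"],
            "class": np.where(cat["synonymous"], "synonymous",
                              "nonsynonymous"),
            "status": np.where(cat["deleterious"], "deleterious", "neutral"),
            "generation": cat["generation"],
        })
    else:
        mutations = pd.DataFrame(columns=_MUT_COLUMNS)
    common = dict(
        params=params, ids=ids_all, parents=np.array(fam.parents),
        birth_generation=np.array(fam.birth_gen),
        n_deleterious=fam.n_del.copy(), alive=alive,
        mutations=mutations, truncated=truncated, n_generations_run=gen,
    )
    if len(alive) < 2:
        return SimulationResult(alignment=None, extinct=True, **common)
    aln = CodonAlignment.from_codes(
        [ids_all[i] for i in alive],
        fam._G[alive],
        family=f"sim-seed{params.seed}",
    )
    return SimulationResult(alignment=aln, extinct=False, **common)


def simulate_families(params: SimParams, n_families: int,
                      seed: int | None = None) -> list[SimulationResult]:
    """Independent replicate families with per-family derived seeds.

    Emulates a multi-family dataset like the five maize families: the unit
    of observation is a family alignment at matched copy number, and
    variant counts are pooled over families.
    """
    base = params.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                   ss.spawn(n_families)]
    return [
        simulate_family(dataclasses.replace(params, seed=child_seed))
        for child_seed in child_seeds
    ]


def simulate_duplication_noise(aln: CodonAlignment, rate: float,
                               seed: int = 0) -> CodonAlignment:
    """Duplicate whole sequences at random (segmental-duplication surrogate).

    Each sequence is independently duplicated with probability ``rate``;
    duplication turns singleton variants of the copied sequence into
    doubletons, the main distortion genome duplication or gene conversion
    would add to the frequency spectrum.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return aln
    rng = np.random.default_rng(seed)
    dup = np.nonzero(rng.random(aln.n_sequences) < rate)[0]
    codes = np.vstack([aln.codes, aln.codes[dup]])
    ids = aln.ids + [f"{aln.ids[i]}_dup" for i in dup]
    return CodonAlignment.from_codes(ids, codes, family=aln.family,
                                     gene=aln.gene)


def to_newick(result: SimulationResult) -> str:
    """Genealogy of every element ever born, as a Newick string.

    Each element appears as a leaf hanging off the transposition events
    that produced its descendants; branch lengths are generation
    differences.
    """
    children: dict[int, list[int]] = {}
    for i, p in enumerate(result.parents):
        if p >= 0:
            children.setdefault(int(p), []).append(i)

    # iterative post-order rendering; genealogies can be deep
    memo: dict[int, str] = {}
    stack = [(0, False)]
    while stack:
        node, expanded = stack.pop()
        kids = children.get(node, [])
        if not expanded:
            stack.append((node, True))
            stack.extend((k, False) for k in kids)
            continue
        leaf = f"{result.ids[node]}:0"
        if not kids:
            memo[node] = leaf
        else:
            parts = [leaf] + [
                "({}):{}".format(
                    memo[c],
                    int(result.birth_generation[c]
                        - result.birth_generation[node]),
                )
                for c in kids
            ]
            memo[node] = "(" + ",".join(parts) + ")"
    return memo[0] + ";"
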