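"""Synthetic protein families with known reference alignments.

Families are evolved down a random binary tree from a root sequence:
substitutions draw replacement residues from a BLOSUM62-derived
stationary distribution, and indels are geometric-length runs whose
homology is tracked exactly — an inserted residue has no homolog in any
other lineage, and a deletion leaves gaps only in the descendants of the
branch it occurred on.  Because every residue's homology is tracked, the
true multiple alignment of the leaves is known by construction, which is
what makes these families usable as references for the Developer Score.

The generator's purpose is controlled identity, not phylogenetic
realism: band suites rejection-sample the per-branch substitution
probability until the reference alignment's identity lands in the
requested band (<20, [20, 40), or [40, 80) percent).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .evaluate import identity
from .seq_core import AA_ORDER, GAP, Alignment, Sequence, write_alignment, write_fasta
from .similarity import default_hmm_params

_BACKGROUND: np.ndarray | None = None


def _background() -> np.ndarray:
    """Stationary residue distribution over the 20 standard residues."""
    global _BACKGROUND
    if _BACKGROUND is None:
        q = default_hmm_params().insert_emit[:20]
        _BACKGROUND = q / q.sum()
    return _BACKGROUND


@dataclass
class EvolutionParams:
    """Controls for one synthetic family."""

    n_leaves: int = 6
    root_length: int = 100
    substitution_rate: float = 0.08  # per-site replacement probability per branch
    insertion_rate: float = 0.02  # per-position insertion-event probability per branch
    deletion_rate: float = 0.02
    indel_mean_length: float = 2.0  # geometric mean run length
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("need at least 2 leaves")
        if self.root_length < 1:
            raise ValueError("root_length must be positive")
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not (0.0 <= r < 1.0):
                raise ValueError("rates must lie in [0, 1)")
        if self.indel_mean_length < 1.0:
            raise ValueError("indel_mean_length must be >= 1")


def _random_topology(n: int, rng: np.random.Generator) -> list:
    """Random binary join order encoded as nested lists of leaf indices."""
    nodes: list = list(range(n))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append([a, b])
    return nodes[0]


def _evolve_branch(
    seq: list[tuple[int, int]],
    params: EvolutionParams,
    rng: np.random.Generator,
    master: list[int],
    next_site: list[int],
) -> list[tuple[int, int]]:
    """One branch of evolution on a list of (site id, residue code)."""
    bg = _background()
    p_geo = 1.0 / params.indel_mean_length

    out: list[tuple[int, int]] = []
    # substitutions and deletions in one left-to-right pass
    skip = 0
    for site, res in seq:
        if skip > 0:
            skip -= 1
            continue
        if rng.random() < params.deletion_rate:
            skip = rng.geometric(p_geo) - 1
            continue
        if rng.random() < params.substitution_rate:
            new = int(rng.choice(20, p=bg))
            while new == res:
                new = int(rng.choice(20, p=bg))
            res = new
        out.append((site, res))

    # insertions: before each surviving position and at the end
    final: list[tuple[int, int]] = []

    def fresh_run(anchor_index: int) -> list[tuple[int, int]]:
        length = int(rng.geometric(p_geo))
        run = []
        for _ in range(length):
            site = next_site[0]
            next_site[0] += 1
            master.insert(anchor_index, site)
            anchor_index += 1
            run.append((site, int(rng.choice(20, p=bg))))
        return run

    for site, res in out:
        if rng.random() < params.insertion_rate:
            final.extend(fresh_run(master.index(site)))
        final.append((site, res))
    if rng.random() < params.insertion_rate:
        final.extend(fresh_run(len(master)))
    return final


def generate_family(
    params: EvolutionParams, max_retries: int = 20
) -> tuple[list[Sequence], Alignment, dict]:
    """Evolve one family; returns (unaligned sequences, reference, metadata).

    The reference de-gaps to exactly the unaligned outputs.  Degenerate
    draws (an empty leaf, or an unalignable reference) are retried with
    perturbed seeds up to ``max_retries`` times.
    """
    for attempt in range(max_retries):
        seed = (params.seed + attempt * 1_000_003) % (2**31)
        rng = np.random.default_rng(seed)
        result = _generate_once(params, rng)
        if result is not None:
            seqs, ref, meta = result
            meta["seed_used"] = seed
            meta["params"] = asdict(params)
            return seqs, ref, meta
    raise RuntimeError(
        f"could not generate a valid family in {max_retries} attempts"
    )


def _generate_once(params: EvolutionParams, rng: np.random.Generator):
    bg = _background()
    topology = _random_topology(params.n_leaves, rng)
    master = list(range(params.root_length))
    next_site = [params.root_length]
    root_seq = [
        (s, int(rng.choice(20, p=bg))) for s in range(params.root_length)
    ]

    leaf_seqs: dict[int, list[tuple[int, int]]] = {}

    def descend(node, seq) -> None:
        if isinstance(node, int):
            leaf_seqs[node] = seq
            return
        for child in node:
            evolved = _evolve_branch(seq, params, rng, master, next_site)
            descend(child, evolved)

    descend(topology, root_seq)
    if any(len(s) == 0 for s in leaf_seqs.values()):
        return None

    ids = [f"seq{i + 1}" for i in range(params.n_leaves)]
    present = set()
    for s in leaf_seqs.values():
        present.update(site for site, _ in s)
    columns = [s for s in master if s in present]
    col_index = {s: k for k, s in enumerate(columns)}

    rows = []
    for i in range(params.n_leaves):
        row = [GAP] * len(columns)
        for site, res in leaf_seqs[i]:
            row[col_index[site]] = AA_ORDER[res]
        rows.append("".join(row))
    try:
        ref = Alignment(ids, rows)
        ident = identity(ref)
    except ValueError:
        return None
    seqs = [Sequence(i, r.replace(GAP, "")) for i, r in zip(ids, rows)]
    meta = {"identity": ident, "n": params.n_leaves, "columns": len(columns)}
    return seqs, ref, meta


BAND_RANGES = {1: (0.0, 20.0), 2: (20.0, 40.0), 3: (40.0, 80.0)}
# per-branch substitution-probability sampling windows per target band
_BAND_SUB_RATES = {1: (0.28, 0.50), 2: (0.14, 0.30), 3: (0.04, 0.15)}


@dataclass
class FamilyInstance:
    instance_id: str
    sequences: list[Sequence]
    reference: Alignment
    metadata: dict


def generate_band_suite(
    band: int,
    n_instances: int,
    seed: int,
    *,
    n_leaves: int = 6,
    root_length: int = 100,
    max_tries: int = 400,
) -> list[FamilyInstance]:
    """Rejection-sample families until each reference identity is in band."""
    if band not in BAND_RANGES:
        raise ValueError("band must be 1, 2 or 3")
    lo, hi = BAND_RANGES[band]
    rate_lo, rate_hi = _BAND_SUB_RATES[band]
    rng = np.random.default_rng(seed)
    out: list[FamilyInstance] = []
    tries = 0
    while len(out) < n_instances:
        if tries >= max_tries:
            raise RuntimeError(
                f"band {band} unreachable after {max_tries} tries "
                f"(accepted {len(out)}/{n_instances}; widen the rate window "
                f"or raise max_tries)"
            )
        tries += 1
        params = EvolutionParams(
            n_leaves=n_leaves,
            root_length=root_length,
            substitution_rate=float(rng.uniform(rate_lo, rate_hi)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        seqs, ref, meta = generate_family(params)
        if lo <= meta["identity"] < hi:
            out.append(
                FamilyInstance(
                    instance_id=f"band{band}_{len(out) + 1:03d}",
                    sequences=seqs,
                    reference=ref,
                    metadata=meta,
                )
            )
    return out


def write_instance(instance: FamilyInstance, out_dir: str | Path) -> Path:
    """Emit one instance directory: sequences.fasta, reference.fasta, metadata."""
    d = Path(out_dir) / instance.instance_id
    d.mkdir(parents=True, exist_ok=True)
    write_fasta(instance.sequences, d / "sequences.fasta")
    write_alignment(instance.reference, d / "reference.fasta", "fasta")
    with open(d / "metadata.json", "w") as fh:
        json.dump(instance.metadata, fh, indent=2)
    return d
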