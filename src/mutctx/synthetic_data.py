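"""Generators emulating every input the analysis pipeline consumes.

The centrepiece is a planted context signature for mutations at cytosines:
sites are drawn with probability proportional to per-position base weights
over the oriented context (a product across positions — the signature
factorises, with CpG coupling handled by a separate multiplier), mimicking a
deaminase that prefers a thymine directly 5' of the target cytosine and
avoids adenine there.  With uniform weights the generator samples sites
proportional to their abundance, i.e. exactly from the background context
distribution, so the null pipeline is honestly calibrated.

All generators are fully determined by (parameters, seed).  Each derives its
own substream from the global seed by stable hashing of the generator name,
so adding a generator does not shift the outputs of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mutctx.assay_stats import ExpressionMatrix, FluctuationAssay
from mutctx.clone_mutations import CloneSet
from mutctx.context import BASES
from mutctx.formats_io import MutationRecord, ReferenceSet, revcomp

_CHANGES = ("C>T", "C>G", "C>A")


def _rng(seed: int, name: str) -> np.random.Generator:
    """Substream for one generator: stable hash of the name mixed with the seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def _norm_weights(w: Mapping[str, float]) -> dict[str, float]:
    total = sum(w.get(b, 0.0) for b in BASES)
    if total <= 0:
        raise ValueError("weights must have positive total")
    return {b: w.get(b, 0.0) / total for b in BASES}


@dataclass
class SignatureSpec:
    """Planted context signature for mutations at cytosines.

    ``position_weights`` maps each flanking position (-flank..+flank, except 0,
    which is fixed to C) to base weights; omitted positions are uniform.
    ``change_probs`` gives the distribution over oriented C>T / C>G / C>A
    changes.  ``cpg_multiplier`` (>= 1) multiplies the sampling weight of CpG
    sites, emulating the excess of transitions at methylated CpGs.
    ``at_fraction`` is the fraction of background mutations placed at A/T
    sites with a uniform random alternate base.
    """

    flank: int = 1
    position_weights: dict[int, dict[str, float]] = field(default_factory=dict)
    change_probs: dict[str, float] = field(
        default_factory=lambda: {"C>T": 0.7, "C>G": 0.2, "C>A": 0.1}
    )
    cpg_multiplier: float = 2.0
    at_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.flank < 1:
            raise ValueError("flank must be >= 1")
        if self.cpg_multiplier < 1:
            raise ValueError("cpg_multiplier must be >= 1")
        if not 0 <= self.at_fraction < 1:
            raise ValueError("at_fraction must be in [0, 1)")
        for pos in list(self.position_weights):
            if pos == 0 or abs(pos) > self.flank:
                raise ValueError(f"weight position {pos} invalid for flank {self.flank}")
            self.position_weights[pos] = _norm_weights(self.position_weights[pos])
        s = sum(self.change_probs.get(c, 0.0) for c in _CHANGES)
        if not np.isclose(s, 1.0):
            raise ValueError("change_probs must sum to 1 over C>T/C>G/C>A")

    def weight_of_context(self, context: str) -> float:
        """Sampling weight of an oriented context (product over positions)."""
        if len(context) != 2 * self.flank + 1:
            raise ValueError("context length inconsistent with flank")
        w = 1.0
        for pos, weights in self.position_weights.items():
            w *= weights[context[self.flank + pos]]
        if context[self.flank + 1] == "G":
            w *= self.cpg_multiplier
        return w


def apobec1_like_signature(flank: int = 1) -> SignatureSpec:
    """The default deaminase-style signature: T preferred, A avoided at -1."""
    return SignatureSpec(
        flank=flank,
        position_weights={-1: {"T": 0.6, "C": 0.25, "G": 0.1, "A": 0.05}},
    )


def uniform_signature(flank: int = 1) -> SignatureSpec:
    """Null signature: sites drawn from the background context distribution."""
    return SignatureSpec(flank=flank, position_weights={}, cpg_multiplier=1.0, at_fraction=0.0)


def gen_reference(
    n_seqs: int = 1,
    length: int = 100_000,
    base_probs: Mapping[str, float] | None = None,
    seed: int = 0,
) -> ReferenceSet:
    """Random reference sequences with the given base composition."""
    if n_seqs < 1:
        raise ValueError("n_seqs must be >= 1")
    probs = base_probs or {b: 0.25 for b in BASES}
    p = np.array([probs[b] for b in BASES], dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("base_probs must sum to 1")
    rng = _rng(seed, "gen_reference")
    basearr = np.array(list(BASES))
    seqs = {
        f"synth{i + 1}": "".join(basearr[rng.choice(4, size=length, p=p)])
        for i in range(n_seqs)
    }
    return ReferenceSet(sequences=seqs)


def _enumerate_c_sites(ref: ReferenceSet, flank: int):
    """All C/G positions with complete N-free windows, with oriented contexts."""
    names, positions, contexts, is_g = [], [], [], []
    for name, seq in ref.sequences.items():
        n = len(seq)
        for i in range(flank, n - flank):
            base = seq[i]
            if base not in "CG":
                continue
            window = seq[i - flank : i + flank + 1]
            if "N" in window:
                continue
            names.append(name)
            positions.append(i)
            contexts.append(window if base == "C" else revcomp(window))
            is_g.append(base == "G")
    return names, positions, contexts, np.array(is_g)


def gen_mutations(
    ref: ReferenceSet,
    n: int,
    sig: SignatureSpec | None = None,
    n_samples: int = 1,
    seed: int = 0,
    unique_sites: bool = False,
) -> list[MutationRecord]:
    """Somatic SNVs with a planted cytosine-context signature.

    Cytosine sites (both strands) are drawn with probability proportional to
    the signature weight of their oriented context; the oriented alternate
    base follows the signature's change distribution; mutations at minus-
    strand cytosines are emitted as genomic G>X records.  A ``sig.at_fraction``
    share of the mutations is placed at A/T sites with a uniform alternate.
    Samples are assigned round-robin.
    """
    sig = sig or apobec1_like_signature()
    rng = _rng(seed, "gen_mutations")
    names, positions, contexts, is_g = _enumerate_c_sites(ref, sig.flank)
    if not names:
        raise ValueError("reference has no usable cytosine site")
    weights = np.array([sig.weight_of_context(c) for c in contexts])
    if weights.sum() <= 0:
        raise ValueError("signature assigns zero weight to every site")
    n_at = int(round(n * sig.at_fraction))
    n_c = n - n_at
    if unique_sites and n_c > len(names):
        raise ValueError(f"requested {n_c} unique cytosine sites, only {len(names)} available")
    probs = weights / weights.sum()
    idx = rng.choice(len(names), size=n_c, replace=not unique_sites, p=probs)
    change_p = np.array([sig.change_probs[c] for c in _CHANGES])
    alts_oriented = rng.choice([c.split(">")[1] for c in _CHANGES], size=n_c, p=change_p)

    comp = dict(zip("ACGT", "TGCA"))
    records: list[MutationRecord] = []
    for k, (i, alt) in enumerate(zip(idx, alts_oriented)):
        if is_g[i]:
            ref_base, alt_base = "G", comp[alt]
        else:
            ref_base, alt_base = "C", alt
        records.append(
            MutationRecord(
                sample_id=f"s{k % n_samples + 1}",
                seq_name=names[i],
                pos=positions[i] + 1,
                ref=ref_base,
                alt=alt_base,
            )
        )
    # background noise at A/T sites
    if n_at > 0:
        at_sites = [
            (name, i)
            for name, seq in ref.sequences.items()
            for i in range(len(seq))
            if seq[i] in "AT"
        ]
        if not at_sites:
            raise ValueError("at_fraction > 0 but reference has no A/T site")
        pick = rng.choice(len(at_sites), size=n_at, replace=True)
        for k, j in enumerate(pick, start=n_c):
            name, i = at_sites[j]
            ref_base = ref.sequences[name][i]
            alt_base = str(rng.choice([b for b in BASES if b != ref_base]))
            records.append(
                MutationRecord(
                    sample_id=f"s{k % n_samples + 1}",
                    seq_name=name,
                    pos=i + 1,
                    ref=ref_base,
                    alt=alt_base,
                )
            )
    return records


def gen_uniform_snvs(
    ref: ReferenceSet, n: int, n_samples: int = 1, seed: int = 0
) -> list[MutationRecord]:
    """Uniform random SNVs: uniform site, uniform alternate base.

    Each site offers one transition and two transversions, so the expected
    Ts/Tv ratio is 0.5 — the null against which a transition excess is read.
    """
    rng = _rng(seed, "gen_uniform_snvs")
    sites = [
        (name, i)
        for name, seq in ref.sequences.items()
        for i in range(len(seq))
        if seq[i] in "ACGT"
    ]
    if not sites:
        raise ValueError("reference has no unambiguous site")
    pick = rng.choice(len(sites), size=n, replace=True)
    records = []
    for k, j in enumerate(pick):
        name, i = sites[j]
        ref_base = ref.sequences[name][i]
        alt_base = str(rng.choice([b for b in BASES if b != ref_base]))
        records.append(
            MutationRecord(
                sample_id=f"s{k % n_samples + 1}",
                seq_name=name,
                pos=i + 1,
                ref=ref_base,
                alt=alt_base,
            )
        )
    return records


def gen_clone_set(
    ref_region: str,
    n_clones: int = 20,
    per_base_rate: float = 1e-3,
    clonal_mutations: Sequence[tuple[int, str]] = (),
    seed: int = 0,
    population: str = "synthetic_population",
) -> CloneSet:
    """Clone sequences with independent per-base substitutions plus shared clonal ones.

    ``clonal_mutations`` is a list of (1-based pos, alt) planted in every clone
    (a clonal expansion); independent substitutions arise per clone per base at
    ``per_base_rate`` with a uniform alternate.
    """
    if not 0 <= per_base_rate <= 0.01:
        raise ValueError("per_base_rate must be in [0, 0.01]")
    rng = _rng(seed, "gen_clone_set")
    L = len(ref_region)
    for pos, alt in clonal_mutations:
        if not 1 <= pos <= L:
            raise ValueError(f"clonal mutation position {pos} outside region")
        if alt == ref_region[pos - 1]:
            raise ValueError(f"clonal mutation at {pos} equals the reference base")
    clones = []
    for c in range(n_clones):
        seq = list(ref_region)
        for pos, alt in clonal_mutations:
            seq[pos - 1] = alt
        if per_base_rate > 0:
            hits = np.flatnonzero(rng.random(L) < per_base_rate)
            for i in hits:
                current = seq[i]
                if current not in "ACGT":
                    continue
                seq[i] = str(rng.choice([b for b in BASES if b != current]))
        clones.append((f"clone{c + 1}", "".join(seq)))
    return CloneSet(
        population=population, ref_name="region", ref_seq=ref_region, clones=clones
    )


def gen_fluctuation(
    constructs: Mapping[str, float],
    n_cultures: int = 12,
    plated: int = 10**8,
    seed: int = 0,
) -> FluctuationAssay:
    """Fluctuation-assay colony counts: resistant ~ Binomial(plated, frequency)."""
    for name, f in constructs.items():
        if not 0 <= f <= 1e-3:
            raise ValueError(f"true frequency for {name!r} must be in [0, 1e-3]")
    rng = _rng(seed, "gen_fluctuation")
    rows = []
    for name, f in constructs.items():
        counts = rng.binomial(plated, f, size=n_cultures)
        for i, c in enumerate(counts):
            rows.append(
                {
                    "culture_id": f"{name}_c{i + 1}",
                    "construct": name,
                    "resistant": int(c),
                    "plated": plated,
                }
            )
    return FluctuationAssay(cultures=pd.DataFrame(rows))


def gen_expression(
    n_genes: int = 200,
    groups: Mapping[str, int] | None = None,
    target_gene_effects: Mapping[str, float] | None = None,
    seed: int = 0,
    target_gene: str = "APOBEC1",
    ref_gene: str = "TBP",
    noise_sd: float = 0.5,
) -> ExpressionMatrix:
    """Log-normal expression matrix with one group-shifted target gene.

    Background genes are i.i.d. log-normal across samples; the target gene is
    shifted per group by the stated log2 effects (e.g. strong upregulation in
    metaplastic and tumour groups).  The reference housekeeping gene is
    generated flat with small noise.
    """
    groups = dict(groups or {"normal": 10, "barrett": 10, "eac": 10})
    effects = dict(target_gene_effects or {g: 0.0 for g in groups})
    rng = _rng(seed, "gen_expression")
    samples, labels = [], {}
    for g, k in groups.items():
        for i in range(k):
            s = f"{g}_{i + 1}"
            samples.append(s)
            labels[s] = g
    gene_names = [target_gene, ref_gene] + [f"gene{i + 1}" for i in range(n_genes - 2)]
    base_log2 = rng.normal(6.0, 1.0, size=n_genes)
    mat = np.empty((n_genes, len(samples)))
    for gi in range(n_genes):
        mat[gi] = base_log2[gi] + rng.normal(0.0, noise_sd, size=len(samples))
    # plant the per-group shifts in the target gene
    ti = gene_names.index(target_gene)
    for si, s in enumerate(samples):
        mat[ti, si] += effects.get(labels[s], 0.0)
    # housekeeping reference: flat, low noise
    ri = gene_names.index(ref_gene)
    mat[ri] = 6.0 + rng.normal(0.0, 0.1, size=len(samples))
    data = pd.DataFrame(np.exp2(mat), index=gene_names, columns=samples)
    return ExpressionMatrix(data=data, groups=labels, ref_gene=ref_gene)
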