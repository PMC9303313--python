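"""Seeded synthetic data with the statistical structure the analysis assumes.

The generator emulates, at desk scale, the three data layers the pipeline
consumes:

* a transcriptome of random transcripts with *planted* near-complementary
  sites at known distance d for configured ASOs, rejection-sampled so that
  no unintended complementary region at d <= d_eff exists -- planted
  distances are therefore unambiguous ground truth;
* expression ratio tables following an RNase H-style knockdown model: the
  mean log2 ratio of a gene at distance d is -delta0 * gamma**d for
  d <= d_eff and 0 otherwise, plus Gaussian noise (geometric decay in d is
  the simplest model consistent with an off-target focus on d <= 2);
* serum toxicity on a log scale, split into a hybridization-dependent term
  proportional to the off-target index (weight beta_hyb) and a per-ASO
  hybridization-independent term beta_indep -- the latent protein-binding
  toxicity that nucleobase modifications reduce in the 'paper_like'
  scenario.

Everything is deterministic per (scenario, seed).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from gapmertox.expression import ExpressionTable, OffTargetIndex, compute_offtarget_index, index_ratio
from gapmertox.gapmer import GapmerASO, parse_gapmer, reverse_complement
from gapmertox.offtarget import GeneDistanceMap, classify_offtargets, scan_transcript, semi_global_distance
from gapmertox.tox import TmRecord, ToxRecord

__all__ = [
    "SimConfig",
    "make_transcriptome",
    "plant_site",
    "simulate_expression",
    "simulate_toxicity",
    "make_fixture_bundle",
    "SCENARIOS",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic study.

    delta0 is the log2 down-regulation of a perfectly complementary (d=0)
    gene; gamma in (0, 1] the geometric decay per unit distance; d_eff the
    largest d with any knockdown (default 2).  alpha is the baseline
    natural-log AST/ALT of a clean ASO (exp(alpha) U/l); beta_hyb weights
    the off-target index and beta_indep holds per-ASO
    hybridization-independent toxicity offsets on the same log scale.
    """

    seed: int = 0
    n_genes: int = 100
    tx_len: tuple[int, int] = (200, 500)
    planted_sites: tuple[tuple[str, str, int], ...] = ()
    delta0: float = 1.0
    gamma: float = 0.5
    d_eff: int = 2
    sigma_expr: float = 0.1
    alpha: float = float(np.log(50.0))
    beta_hyb: float = 0.0
    beta_indep: Mapping[str, float] = field(default_factory=dict)
    sigma_tox: float = 0.1

    def __post_init__(self) -> None:
        if self.delta0 < 0:
            raise ValueError("delta0 must be >= 0")
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must be in (0, 1]")
        if self.sigma_expr < 0 or self.sigma_tox < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.tx_len[0] > self.tx_len[1] or self.tx_len[0] < 1:
            raise ValueError("tx_len must be a non-empty (min, max) range")


def _stable_int(label: str) -> int:
    return zlib.crc32(label.encode("utf-8")) & 0x7FFFFFFF


def _rng_for(cfg: SimConfig, label: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed & 0x7FFFFFFF, _stable_int(label)])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _levenshtein(a: str, b: str) -> int:
    """Plain global edit distance; used to certify planted-edit counts."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j - 1] + (ca != cb), prev[j] + 1, cur[-1] + 1))
        prev = cur
    return prev[-1]


def _apply_edits(site: str, d: int, rng: np.random.Generator) -> str:
    """Apply d random edits (substitution/insertion/deletion mix) to a site."""
    s = list(site)
    for _ in range(d):
        op = int(rng.integers(0, 3)) if len(s) > 1 else int(rng.integers(0, 2))
        if op == 0:  # substitution
            pos = int(rng.integers(0, len(s)))
            s[pos] = rng.choice([b for b in _BASES if b != s[pos]])
        elif op == 1:  # insertion
            pos = int(rng.integers(0, len(s) + 1))
            s.insert(pos, _BASES[int(rng.integers(0, 4))])
        else:  # deletion
            pos = int(rng.integers(0, len(s)))
            del s[pos]
    return "".join(s)


def plant_site(
    transcript: str,
    aso: GapmerASO,
    d: int,
    seed: Union[int, np.random.Generator],
    max_tries: int = 200,
) -> tuple[str, tuple[int, int]]:
    """Embed a complementary site at exactly distance ``d`` into a transcript.

    The reverse complement of the ASO sequence is mutated with exactly d
    random edits (certified by a global edit-distance check), inserted at
    a random position, and the modified transcript re-scanned: the minimal
    scan distance must equal the requested d, otherwise the plant is
    regenerated.  Returns the new sequence and the planted half-open
    interval.  Raises after ``max_tries`` failed attempts.
    """
    if not (0 <= d <= 3):
        raise ValueError("planted distance must be between 0 and 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    site = reverse_complement(aso.sequence)
    for _ in range(max_tries):
        mutated = _apply_edits(site, d, rng)
        if _levenshtein(site, mutated) != d or not mutated:
            continue
        pos = int(rng.integers(0, len(transcript) + 1))
        cand = transcript[:pos] + mutated + transcript[pos:]
        hits = scan_transcript(aso, ("_plant_check", cand), d_max=3)
        if hits and min(h.d for h in hits) == d:
            return cand, (pos, pos + len(mutated))
    raise RuntimeError(
        f"could not plant a d={d} site for {aso.id} after {max_tries} tries"
    )


def _unique_patterns(asos: Sequence[GapmerASO]) -> dict[str, str]:
    """Distinct ASO sequences -> search pattern (reverse complement)."""
    return {a.sequence: reverse_complement(a.sequence) for a in asos}


def make_transcriptome(
    cfg: SimConfig,
    asos: Sequence[GapmerASO] = (),
    max_tries: int = 100,
) -> tuple[dict[str, str], dict[str, str]]:
    """Generate a clean random transcriptome, then plant configured sites.

    One transcript per gene (ids ``txNNNN`` / ``geneNNNN``).  Each raw
    transcript is rejection-sampled until it has no complementary region
    at d <= ``cfg.d_eff`` to any configured ASO; ``cfg.planted_sites``
    (aso_id, gene_id, d) triples are then embedded via :func:`plant_site`,
    re-checking that a plant for one ASO does not create an accidental
    match for another.  Deterministic per seed.
    """
    rng = _rng_for(cfg, "transcriptome")
    patterns = _unique_patterns(asos)
    by_name: dict[str, GapmerASO] = {a.id: a for a in asos}
    lo, hi = cfg.tx_len
    transcripts: dict[str, str] = {}
    tx2gene: dict[str, str] = {}
    gene2tx: dict[str, str] = {}
    for i in range(1, cfg.n_genes + 1):
        tid, gene = f"tx{i:04d}", f"gene{i:04d}"
        for _ in range(max_tries):
            seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
            if all(semi_global_distance(p, seq) > cfg.d_eff for p in patterns.values()):
                break
        else:
            raise RuntimeError(
                "transcript rejection budget exceeded; try longer transcripts or fewer ASOs"
            )
        transcripts[tid] = seq
        tx2gene[tid] = gene
        gene2tx[gene] = tid
    for aso_id, gene_id, d in cfg.planted_sites:
        if aso_id not in by_name:
            raise KeyError(f"planted site references unknown ASO {aso_id!r}")
        if gene_id not in gene2tx:
            raise KeyError(f"planted site references unknown gene {gene_id!r}")
        aso = by_name[aso_id]
        tid = gene2tx[gene_id]
        others = [p for s, p in patterns.items() if s != aso.sequence]
        for _ in range(max_tries):
            new_seq, _interval = plant_site(transcripts[tid], aso, d, rng)
            if all(semi_global_distance(p, new_seq) > cfg.d_eff for p in others):
                transcripts[tid] = new_seq
                break
        else:
            raise RuntimeError(f"could not plant d={d} for {aso_id} without cross-ASO conflicts")
    return transcripts, tx2gene


def simulate_expression(
    cfg: SimConfig,
    dist: GeneDistanceMap,
    aso_id: str,
    gene_ids: Sequence[str],
    rng: Optional[np.random.Generator] = None,
) -> ExpressionTable:
    """Draw per-gene expression ratios under the geometric knockdown model.

    log2 ratio = -delta0 * gamma**d(g) for d(g) <= d_eff (0 otherwise)
    plus Normal(0, sigma_expr) noise; genes with no hit get pure noise.
    A lognormal ``control_intensity`` column is included for scatter-style
    summaries.  Deterministic per (cfg.seed, aso_id) when no rng is given.
    """
    if rng is None:
        rng = _rng_for(cfg, f"expression:{aso_id}")
    import pandas as pd

    mu = np.array(
        [
            -cfg.delta0 * cfg.gamma ** dist.min_d[g]
            if g in dist.min_d and dist.min_d[g] <= cfg.d_eff
            else 0.0
            for g in gene_ids
        ]
    )
    noise = rng.normal(0.0, cfg.sigma_expr, size=len(mu)) if cfg.sigma_expr > 0 else 0.0
    log2_ratio = mu + noise
    intensity = np.exp(rng.normal(8.0, 1.5, size=len(mu)))
    frame = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "ratio": np.exp2(log2_ratio),
            "control_intensity": intensity,
        }
    )
    return ExpressionTable(aso_id=aso_id, data=frame)


def simulate_toxicity(
    cfg: SimConfig,
    indices: Mapping[str, Union[float, OffTargetIndex]],
    rng: Optional[np.random.Generator] = None,
    dose: float = 20.0,
) -> list[ToxRecord]:
    """Draw serum AST/ALT per ASO on the two-component log-linear model.

    ln AST = alpha + beta_hyb * index + beta_indep[aso] + Normal(0,
    sigma_tox); ALT uses the same mean with independent noise.
    """
    if rng is None:
        rng = _rng_for(cfg, "toxicity")
    records = []
    for aso_id in indices:
        idx = indices[aso_id]
        value = idx.value if isinstance(idx, OffTargetIndex) else float(idx)
        mu = cfg.alpha + cfg.beta_hyb * value + cfg.beta_indep.get(aso_id, 0.0)
        ast = float(np.exp(mu + rng.normal(0.0, cfg.sigma_tox)))
        alt = float(np.exp(mu + rng.normal(0.0, cfg.sigma_tox)))
        records.append(ToxRecord(aso_id=aso_id, ast=ast, alt=alt, dose=dose, n_animals=4))
    return records


# --------------------------------------------------------------------------
# scenario bundles


def _ts1_family() -> list[GapmerASO]:
    """A parent hepatotoxic gapmer plus single- and triple-modified analogs.

    Same base sequence throughout (modifications are annotations), so the
    family shares one distance map -- the construction that lets the
    off-target index stay flat while toxicity varies.
    """
    parent = parse_gapmer("TS1", "GTTATGCCACCCTA")
    c1 = parse_gapmer("TS1-C1-7", parents={"TS1": parent})
    t1 = parse_gapmer("TS1-T1-5", parents={"TS1": parent})
    g1 = parse_gapmer("TS1-G1-6", parents={"TS1": parent})
    triple = parse_gapmer("TS1", "GTTATGCCACCCTA", mods="G1@6;T1@5;C1@7")
    triple = replace(triple, id="TS1-G1T1C1")
    return [parent, c1, t1, g1, triple]


def _scenario_paper_like(seed: int) -> dict:
    asos = _ts1_family()
    plants = []
    counts = {0: 8, 1: 10, 2: 12, 3: 10}
    g = 0
    for d, n in counts.items():
        for _ in range(n):
            g += 1
            plants.append(("TS1", f"gene{g:04d}", d))
    cfg = SimConfig(
        seed=seed,
        n_genes=160,
        tx_len=(200, 400),
        planted_sites=tuple(plants),
        delta0=1.0,
        gamma=0.5,
        d_eff=2,
        sigma_expr=0.1,
        alpha=float(np.log(50.0)),
        beta_hyb=0.0,
        # hybridization-independent toxicity: high for the parent, cut
        # ~25-300x by single modifications and further by the triple
        beta_indep={
            "TS1": float(np.log(240.0)),
            "TS1-C1-7": float(np.log(240.0 * 0.007)),
            "TS1-T1-5": float(np.log(240.0 * 0.041)),
            "TS1-G1-6": float(np.log(240.0 * 0.022)),
            "TS1-G1T1C1": float(np.log(240.0 * 0.003)),
        },
        sigma_tox=0.1,
    )
    tm = {
        "TS1": (65.0, None),
        "TS1-C1-7": (58.9, "TS1"),  # C1 destabilizes: drop > 5 degC
        "TS1-T1-5": (64.4, "TS1"),
        "TS1-G1-6": (59.3, "TS1"),  # G1 destabilizes
        "TS1-G1T1C1": (53.6, "TS1"),
    }
    return {"asos": asos, "cfg": cfg, "tm": tm}


def _scenario_hybridization_driven(seed: int) -> dict:
    rng = np.random.default_rng([seed & 0x7FFFFFFF, _stable_int("hyb-asos")])
    asos = []
    n_plants = [0, 2, 4, 6, 8, 10]
    for i in range(6):
        seq = _random_seq(rng, 14)
        asos.append(parse_gapmer(f"HYB{i + 1}", seq))
    plants = []
    g = 0
    for aso, n in zip(asos, n_plants):
        for _ in range(n):
            g += 1
            plants.append((aso.id, f"gene{g:04d}", 0))
    cfg = SimConfig(
        seed=seed,
        n_genes=80,
        tx_len=(200, 400),
        planted_sites=tuple(plants),
        delta0=1.0,
        gamma=0.5,
        d_eff=2,
        sigma_expr=0.1,
        alpha=float(np.log(50.0)),
        beta_hyb=0.35,
        beta_indep={},
        sigma_tox=0.05,
    )
    tm = {a.id: (64.0, None) for a in asos}
    return {"asos": asos, "cfg": cfg, "tm": tm}


def _scenario_null(seed: int) -> dict:
    rng = np.random.default_rng([seed & 0x7FFFFFFF, _stable_int("null-asos")])
    asos = [parse_gapmer(f"NULL{i + 1}", _random_seq(rng, 14)) for i in range(3)]
    cfg = SimConfig(
        seed=seed,
        n_genes=40,
        tx_len=(200, 400),
        delta0=1.0,
        gamma=0.5,
        d_eff=2,
        sigma_expr=0.1,
        alpha=float(np.log(50.0)),  # baseline well below the 100 U/l call
        beta_hyb=0.0,
        beta_indep={},
        sigma_tox=0.1,
    )
    tm = {a.id: (64.0, None) for a in asos}
    return {"asos": asos, "cfg": cfg, "tm": tm}


SCENARIOS = {
    "paper_like": _scenario_paper_like,
    "hybridization_driven": _scenario_hybridization_driven,
    "null": _scenario_null,
}


def make_fixture_bundle(scenario: str, seed: int, out_dir: Union[str, Path, None] = None) -> dict:
    """Build a self-consistent fixture bundle for one scenario.

    Scenarios: ``paper_like`` (one parent + modified analogs sharing a
    sequence; toxicity differences are hybridization-independent),
    ``hybridization_driven`` (distinct ASOs whose toxicity tracks their
    off-target index), ``null`` (clean ASOs, baseline chemistry).

    Returns a manifest dict with all parameters, per-ASO indices, toxicity
    and Tm values; when ``out_dir`` is given, writes transcriptome FASTA,
    tx2gene/asos/distances/expression/tox/tm TSVs and manifest.json in the
    exact formats the analysis modules consume.  Byte-identical output per
    (scenario, seed).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    scenario_spec = SCENARIOS[scenario](seed)
    asos: list[GapmerASO] = scenario_spec["asos"]
    cfg: SimConfig = scenario_spec["cfg"]
    transcripts, tx2gene = make_transcriptome(cfg, asos)
    gene_ids = sorted(set(tx2gene.values()))
    # one distance map per unique sequence, shared by annotation variants
    dist_by_seq: dict[str, GeneDistanceMap] = {}
    dist_maps: dict[str, GeneDistanceMap] = {}
    for aso in asos:
        if aso.sequence not in dist_by_seq:
            dist_by_seq[aso.sequence] = classify_offtargets(aso, transcripts, tx2gene, d_max=3)
        base = dist_by_seq[aso.sequence]
        dist_maps[aso.id] = GeneDistanceMap(aso_id=aso.id, min_d=dict(base.min_d))
    expr_tables = {
        aso.id: simulate_expression(cfg, dist_maps[aso.id], aso.id, gene_ids) for aso in asos
    }
    indices = {
        aso.id: compute_offtarget_index(expr_tables[aso.id], dist_maps[aso.id], d_cutoff=2)
        for aso in asos
    }
    tox_records = simulate_toxicity(cfg, indices)
    tm_records = [
        TmRecord(aso_id=aid, tm=tm, source="measured", parent_id=parent)
        for aid, (tm, parent) in scenario_spec["tm"].items()
    ]
    parent_id = asos[0].id
    derived: dict[str, dict[str, float]] = {"index": {}, "index_ratio_pct": {}, "ast": {}, "alt": {}}
    tox_by_id = {r.aso_id: r for r in tox_records}
    for aso in asos:
        derived["index"][aso.id] = round(indices[aso.id].value, 6)
        derived["ast"][aso.id] = round(tox_by_id[aso.id].ast, 3)
        derived["alt"][aso.id] = round(tox_by_id[aso.id].alt, 3)
        if aso.id != parent_id and indices[parent_id].value > 0:
            derived["index_ratio_pct"][aso.id] = round(
                index_ratio(indices[aso.id], indices[parent_id]), 3
            )
    manifest = {
        "scenario": scenario,
        "seed": seed,
        "parameters": {
            "n_genes": cfg.n_genes,
            "tx_len": list(cfg.tx_len),
            "delta0": cfg.delta0,
            "gamma": cfg.gamma,
            "d_eff": cfg.d_eff,
            "sigma_expr": cfg.sigma_expr,
            "alpha": cfg.alpha,
            "beta_hyb": cfg.beta_hyb,
            "beta_indep": dict(cfg.beta_indep),
            "sigma_tox": cfg.sigma_tox,
        },
        "asos": [aso.id for aso in asos],
        "parent": parent_id,
        "planted_sites": [list(p) for p in cfg.planted_sites],
        "derived": derived,
    }
    if out_dir is not None:
        _write_bundle(Path(out_dir), manifest, asos, transcripts, tx2gene, dist_maps,
                      expr_tables, tox_records, tm_records)
    return manifest


def _write_bundle(out, manifest, asos, transcripts, tx2gene, dist_maps,
                  expr_tables, tox_records, tm_records) -> None:
    import pandas as pd

    from gapmertox.io import write_fasta, write_gapmer_tsv, write_tx2gene

    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "transcriptome.fa", transcripts)
    write_tx2gene(out / "tx2gene.tsv", tx2gene)
    renamed = [replace(a, id=a.id) for a in asos]
    write_gapmer_tsv(out / "asos.tsv", renamed)
    pd.concat([m.to_frame() for m in dist_maps.values()]).to_csv(
        out / "distances.tsv", sep="\t", index=False
    )
    for aso_id, table in expr_tables.items():
        table.data.to_csv(out / f"expression_{aso_id}.tsv", sep="\t", index=False,
                          float_format="%.6f")
    pd.DataFrame(
        [
            {"aso_id": r.aso_id, "ast": f"{r.ast:.3f}", "alt": f"{r.alt:.3f}",
             "dose": r.dose, "n_animals": r.n_animals}
            for r in tox_records
        ]
    ).to_csv(out / "tox.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"aso_id": r.aso_id, "tm": r.tm, "source": r.source,
             "parent_id": r.parent_id if r.parent_id is not None else ""}
            for r in tm_records
        ]
    ).to_csv(out / "tm.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
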