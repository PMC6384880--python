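"""End-to-end pipeline: simulate → align → variants → spectrum → Dollo →
rearrangements → dN/dS → CAI → report.

A :class:`RunConfig` selects stages and carries every tunable; stages
communicate through files in the run directory, so any contiguous subset of
stages can be re-run. ``summary.json`` (the machine-readable report) is
written with sorted keys and no timestamps, so a fixed seed reproduces it
byte-identically; timings and checksums go to ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import align as A
from . import dollo as D
from . import rearrange as R
from . import selection as S
from .spectrum import (
    directional_chi_square,
    equilibrium_gc,
    indel_direction_and_homopolymers,
    polarize,
    spectrum as compute_spectrum,
)
from .genome import AnnotatedGenome
from .simulate import (
    AncestorSpec,
    EvolutionParams,
    TruthLog,
    evolve_tree,
    generate_ancestor,
    load_dated_tree,
)

log = logging.getLogger("endosym")

STAGE_ORDER = (
    "simulate",
    "align",
    "variants",
    "spectrum",
    "dollo",
    "rearrange",
    "dnds",
    "cai",
    "report",
)


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run. Unknown keys rejected."""

    outdir: str = "endosym_run"
    stages: tuple = STAGE_ORDER
    seed: int = 0
    # --- simulate
    ancestor: dict = field(default_factory=dict)  # AncestorSpec overrides
    evolution: dict = field(default_factory=dict)  # EvolutionParams overrides
    # --- roles
    outgroup: str = "NZ27"
    ingroups: tuple = ("KR01", "FK01")
    # --- externally supplied inputs (instead of the simulate stage)
    genomes: dict = field(default_factory=dict)  # id -> {"fasta":…, "gff3":…}
    tree: str | None = None
    presence_matrix: str | None = None
    min_taxa_filter: int = 0
    # --- alignment
    anchor_k: int = 21
    band: int = 16
    rotate_gene: str | None = None
    # --- selection metrics
    ds_window: tuple = (0.01, 2.0)
    cai_floor: float = 0.01
    n_dnds_genes: int = 60

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        bad = set(self.stages) - set(STAGE_ORDER)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if len(self.ingroups) != 2:
            raise ValueError("exactly two ingroups required")
        lo, hi = self.ds_window
        if not 0 <= lo < hi:
            raise ValueError("ds_window must satisfy 0 ≤ lo < hi")
        AncestorSpec(**{**self.ancestor, "rng_seed": 0}).validate()
        EvolutionParams(**{**self.evolution, "seed": 0}).validate()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    """Executes the configured stages in dependency order."""

    def __init__(self, config: RunConfig):
        config.validate()
        self.cfg = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.summary: dict = {}
        self.manifest: dict = {"stages": {}, "checksums": {}}
        self._genomes: dict[str, AnnotatedGenome] = {}
        self._truth: TruthLog | None = None
        self._threeway = None
        self._variants = None
        self._pv = None
        self._spectrum = None

    # ------------------------------------------------------------ plumbing

    def _load_genomes(self) -> dict:
        if self._genomes:
            return self._genomes
        if self.cfg.genomes:
            for gid, paths in self.cfg.genomes.items():
                g = AnnotatedGenome.from_files(paths["fasta"], paths.get("gff3"))
                g.id = gid
                self._genomes[gid] = g
        else:
            for fa in sorted(self.out.glob("genome_*.fasta")):
                gid = fa.stem.replace("genome_", "")
                gff = fa.with_suffix(".gff3")
                g = AnnotatedGenome.from_files(fa, gff if gff.exists() else None)
                g.id = gid
                self._genomes[gid] = g
        if not self._genomes:
            raise RuntimeError(
                "no genomes available: run the simulate stage or configure inputs"
            )
        return self._genomes

    def _need(self, name: str, value):
        if value is None:
            raise RuntimeError(f"missing dependency output: stage {name!r} not run")
        return value

    def _tree_str(self) -> str:
        if self.cfg.tree:
            return self.cfg.tree
        return EvolutionParams(**{**self.cfg.evolution}).tree

    @staticmethod
    def _graft_root_leaf(newick: str, label: str) -> "object":
        """Attach ``label`` as a zero-length leaf at the root."""
        tree = load_dated_tree(newick)
        nd = tree.seed_node.new_child(edge_length=0.0)
        nd.taxon = tree.taxon_namespace.new_taxon(label=label)
        return tree

    # -------------------------------------------------------------- stages

    def stage_simulate(self) -> None:
        spec = AncestorSpec(**{**self.cfg.ancestor})
        if "rng_seed" not in self.cfg.ancestor:
            spec.rng_seed = self.cfg.seed
        params = EvolutionParams(**{**self.cfg.evolution})
        if "seed" not in self.cfg.evolution:
            params.seed = self.cfg.seed + 1
        ancestor = generate_ancestor(spec)
        leaves, truth = evolve_tree(ancestor, params)
        self._genomes = {"ancestor": ancestor, **leaves}
        self._truth = truth
        for gid, g in self._genomes.items():
            g.to_fasta(self.out / f"genome_{gid}.fasta")
            g.to_gff3(self.out / f"genome_{gid}.gff3")
        truth.write_jsonl(self.out / "truth.jsonl")
        self.summary["simulate"] = {
            "seed": int(spec.rng_seed),
            "evolution_seed": int(params.seed),
            "genomes": sorted(self._genomes),
            "n_substitutions": len(truth.substitutions()),
            "n_indels": len(truth.indels()),
            "n_losses": len(truth.losses()),
            "n_inversions": len(truth.inversions()),
        }

    def stage_align(self) -> None:
        genomes = self._load_genomes()
        out = self.cfg.outgroup
        in1, in2 = self.cfg.ingroups
        gs = {}
        for gid in (out, in1, in2):
            g = genomes[gid]
            if self.cfg.rotate_gene:
                g = g.rotate_to_gene(self.cfg.rotate_gene)
            gs[gid] = g
        a1 = A.align_pair(gs[in1], gs[out], k=self.cfg.anchor_k, band=self.cfg.band)
        a2 = A.align_pair(gs[in2], gs[out], k=self.cfg.anchor_k, band=self.cfg.band)
        self._threeway = A.project_threeway(a1, a2, out)
        self._threeway.write_maf(self.out / "threeway.maf")
        self.summary["align"] = {
            "columns": self._threeway.ncols,
            "rows": sorted(self._threeway.rows),
        }

    def _load_threeway(self):
        if self._threeway is None:
            maf = self.out / "threeway.maf"
            if maf.exists():
                rows = {}
                for line in open(maf):
                    if line.startswith("s "):
                        parts = line.split()
                        rows[parts[1]] = parts[6]
                self._threeway = A.MultiAlignment(rows)
        return self._need("align", self._threeway)

    def stage_variants(self) -> None:
        aln = self._load_threeway()
        genomes = self._load_genomes()
        ref = genomes[self.cfg.outgroup]
        self._variants = A.call_variants(aln, ref.features, self.cfg.outgroup)
        A.write_variants_tsv(
            self._variants, self.out / "variants.tsv", chrom=self.cfg.outgroup
        )
        self.summary["variants"] = A.snp_densities(self._variants, ref)

    def stage_spectrum(self) -> None:
        aln = self._load_threeway()
        genomes = self._load_genomes()
        ref = genomes[self.cfg.outgroup]
        pv = polarize(
            aln, tuple(self.cfg.ingroups), self.cfg.outgroup, tuple(ref.features)
        )
        anc_seq = aln.ungapped(self.cfg.outgroup)
        st = compute_spectrum(pv, anc_seq)
        eq = equilibrium_gc(st)
        chi, pval = directional_chi_square(st)
        n_ins, n_del, net, hp = indel_direction_and_homopolymers(pv, anc_seq)
        self._pv, self._spectrum = pv, st
        st.to_frame().to_csv(self.out / "spectrum_12class.tsv", sep="\t", index=False)
        st.collapsed_frame().to_csv(
            self.out / "spectrum_6class.tsv", sep="\t", index=False
        )
        hp.to_csv(self.out / "homopolymers.tsv", sep="\t", index=False)
        self.summary["spectrum"] = {
            "n_polarized_snps": len(pv.snps),
            "n_polarized_indels": len(pv.indels),
            "n_unpolarizable": pv.n_unpolarizable,
            "n_shared": pv.n_shared,
            "collapsed_pct": {k: round(v, 4) for k, v in st.collapsed_pct.items()},
            "transitions": st.n_transitions,
            "transversions": st.n_transversions,
            "equilibrium_gc_pct": round(eq, 4),
            "observed_gc_pct": round(
                100 * (anc_seq.count("G") + anc_seq.count("C")) / len(anc_seq), 4
            )
            if anc_seq
            else 0.0,
            "chi_square": round(chi, 6),
            "chi_square_p": pval,
            "insertions": n_ins,
            "deletions": n_del,
            "net_bp": net,
        }

    def stage_dollo(self) -> None:
        tree = self._tree_str()
        if self.cfg.presence_matrix:
            mat = D.PresenceAbsenceMatrix.from_tsv(self.cfg.presence_matrix)
        else:
            # Simulated runs anchor the ancestral inventory by grafting the
            # ancestor itself as a zero-length root leaf — the same role the
            # free-living outgroup taxa play on real data. Without such an
            # anchor, losses shared by a whole root subtree are invisible to
            # Dollo parsimony (the gain is simply inferred deeper).
            genomes = self._load_genomes()
            taxa = sorted(genomes)
            presence = {
                gid: {
                    f.family
                    for f in genomes[gid].features
                    if f.kind != "pseudogene" and f.family
                }
                for gid in taxa
            }
            mat = D.PresenceAbsenceMatrix.from_presence(presence, taxa)
            if "ancestor" in genomes:
                tree = self._graft_root_leaf(tree, "ancestor")
        if self.cfg.min_taxa_filter:
            mat = mat.filter_min_taxa(self.cfg.min_taxa_filter)
        recon = D.dollo_reconstruct(mat, tree)
        recon.branch_table().to_csv(
            self.out / "dollo_branches.tsv", sep="\t", index=False
        )
        timelines = D.loss_timeline(recon)
        tree_obj = recon.tree
        root_label = D._label(tree_obj.seed_node)
        root_n = len(recon.node_families[root_label])
        leaf_labels = [t.leaf for t in timelines.values() if t.leaf != "ancestor"]
        root_set = recon.node_families[root_label]
        mean_leaf = float(np.mean(
            [len(recon.node_families[l] & root_set) for l in leaf_labels]
        ))
        self.summary["dollo"] = {
            "n_families": len(mat.families),
            "node_counts": {
                k: len(v) for k, v in sorted(recon.node_families.items())
            },
            "total_losses": recon.total_losses(),
            "root_families": root_n,
            "retained_fraction_pct": round(
                D.retained_fraction(mean_leaf, root_n - mean_leaf), 4
            )
            if root_n
            else 0.0,
            "timelines": {
                leaf: tl.intervals for leaf, tl in sorted(timelines.items())
            },
        }

    def stage_rearrange(self) -> None:
        genomes = self._load_genomes()
        labels = [g for g in sorted(genomes) if g != "ancestor"]
        use = labels + (["ancestor"] if "ancestor" in genomes else [])
        orders = R.single_copy_gene_orders([genomes[g] for g in use])
        blocks = R.blocks_from_gene_orders(orders)
        anc_id = "ancestor" if "ancestor" in blocks else labels[0]
        res = R.tree_inversion_parsimony(
            {k: v for k, v in blocks.items() if k in labels},
            self._tree_str(),
            blocks[anc_id],
        )
        self.summary["rearrange"] = {
            "n_blocks": len(blocks[anc_id].order),
            "block_orders": {k: list(v.order) for k, v in sorted(blocks.items())},
            "per_branch_events": dict(sorted(res["per_branch"].items())),
            "total_events": res["total"],
        }

    def _paired_cds(self):
        """Ancestor-vs-leaf CDS pairs for families untouched by indels."""
        genomes = self._load_genomes()
        if "ancestor" not in genomes:
            raise RuntimeError("dnds/cai stages need simulated genomes")
        anc = genomes["ancestor"]
        pairs = []
        for f in anc.features:
            if f.kind != "CDS":
                continue
            for gid, g in genomes.items():
                if gid == "ancestor":
                    continue
                lf = [
                    x for x in g.features
                    if x.family == f.family and x.kind == "CDS"
                ]
                if len(lf) != 1 or lf[0].length != f.length:
                    continue
                pairs.append((f.family, gid, f.sequence(anc.seq),
                              lf[0].sequence(g.seq)))
        return pairs

    def stage_dnds(self) -> None:
        truth = self._truth
        if truth is None and (self.out / "truth.jsonl").exists():
            truth = self._truth = TruthLog.read_jsonl(self.out / "truth.jsonl")
        pairs = self._paired_cds()
        rng = np.random.default_rng(self.cfg.seed + 7)
        fams = sorted({fam for fam, *_ in pairs})
        if len(fams) > self.cfg.n_dnds_genes:
            fams = sorted(
                rng.choice(fams, size=self.cfg.n_dnds_genes, replace=False)
            )
        records = []
        for fam, gid, s1, s2 in pairs:
            if fam not in fams:
                continue
            try:
                records.append(
                    S.ng86_dnds(s1, s2, gene=fam, pair=f"ancestor:{gid}",
                                ds_window=tuple(self.cfg.ds_window))
                )
            except S.CodonAlignmentError:
                continue
        groups = self._loss_groups(truth)
        rows = [dataclasses.asdict(r) for r in records]
        import pandas as pd

        pd.DataFrame(rows).to_csv(self.out / "dnds_records.tsv", sep="\t", index=False)
        try:
            summ = S.group_dnds_summary(
                records, {g: groups.get(g, "GROUP-1") for g in fams}
            )
        except ValueError as e:
            summ = {"error": str(e)}
        self.summary["dnds"] = {
            "n_records": len(records),
            "n_filtered": sum(r.filtered for r in records),
            **summ,
        }

    def _loss_groups(self, truth: TruthLog | None) -> dict:
        """Synthetic group labels from loss history: retained in all leaves
        (GROUP-1), lost in some lineage after the basal split (GROUP-2),
        lost on the stem (GROUP-3)."""
        if truth is None or not truth.presence:
            return {}
        tree = load_dated_tree(self._tree_str())
        leaves = [
            l.taxon.label for l in tree.leaf_node_iter() if l.taxon is not None
        ]
        leaves = [l for l in leaves if l in truth.presence]
        groups = {}
        all_fams = set().union(*(set(v) for v in truth.presence.values()))
        for fam in all_fams:
            n_leaf = sum(fam in set(truth.presence[l]) for l in leaves)
            if n_leaf == len(leaves):
                groups[fam] = "GROUP-1"
            elif n_leaf > 0:
                groups[fam] = "GROUP-2"
            else:
                groups[fam] = "GROUP-3"
        return groups

    def stage_cai(self) -> None:
        genomes = self._load_genomes()
        anc = genomes.get("ancestor")
        if anc is None:
            raise RuntimeError("cai stage needs simulated genomes")
        counts: dict[str, int] = {}
        for f in anc.features:
            if f.kind != "CDS":
                continue
            s = f.sequence(anc.seq)
            for i in range(0, len(s) - 2, 3):
                counts[s[i : i + 3]] = counts.get(s[i : i + 3], 0) + 1
        usage = S.CodonUsageTable.from_counts(counts)
        usage.to_tsv(self.out / "codon_usage_w.tsv")
        values = {}
        for gid, g in sorted(genomes.items()):
            vals = []
            for f in g.features:
                if f.kind != "CDS":
                    continue
                try:
                    vals.append(S.cai(f.sequence(g.seq), usage,
                                      w_floor=self.cfg.cai_floor))
                except ValueError:
                    continue
            values[gid] = {
                "mean": float(np.mean(vals)) if vals else None,
                "n": len(vals),
            }
        self.summary["cai"] = values

    def stage_report(self) -> None:
        path = self.out / "summary.json"
        with open(path, "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True, default=_json_safe)
            fh.write("\n")

    # ----------------------------------------------------------------- run

    def run(self) -> dict:
        todo = [s for s in STAGE_ORDER if s in self.cfg.stages]
        for stage in todo:
            t0 = time.time()
            log.info("stage %s starting", stage)
            getattr(self, f"stage_{stage}")()
            dt = time.time() - t0
            self.manifest["stages"][stage] = {"seconds": round(dt, 3)}
            log.info("stage %s done in %.2fs", stage, dt)
        for f in sorted(self.out.iterdir()):
            if f.is_file() and f.name != "manifest.json":
                self.manifest["checksums"][f.name] = _sha256(f)
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return self.summary


def _json_safe(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset, tuple)):
        return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run(config: RunConfig) -> dict:
    """Convenience wrapper: build a :class:`Pipeline` and execute it."""
    return Pipeline(config).run()
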