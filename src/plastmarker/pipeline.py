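"""End-to-end orchestration: structure -> SSR -> alignment -> variants ->
Pi -> markers -> phylogeny, from one configuration, with an output manifest.

Stages run in dependency order; a stage failure is recorded in the manifest
and its dependents are skipped, but completed outputs are kept.  With a
fixed configuration and seed the manifest checksums are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import comparative, diversity, io_formats, markers, phylo, ssr, structure

log = logging.getLogger("plastmarker")


@dataclass
class RunConfig:
    fasta: str
    groups: str | None = None
    reference: str | None = None  # default: first record
    annotations: str | None = None  # GenBank or GFF3 for the reference
    alignment: str | None = None  # precomputed aligned FASTA (optional)
    out_dir: str = "plastmarker_out"
    seed: int = 0
    min_ir_len: int = 1000
    ssr_thresholds: str = "1=10,2=5,3=5,4=4,5=3,6=3"
    pi_window: int = 500
    pi_step: int = 250
    hotspot_threshold: float = 0.01
    bootstrap: int = 1000
    outgroup: str | None = None
    model: str = "jc69"
    marker_config: markers.MarkerConfig = field(default_factory=markers.MarkerConfig)
    max_dcaps_loci: int = 4

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mc = raw.pop("marker_config", None)
        cfg = cls(**raw)
        if mc:
            cfg.marker_config = markers.MarkerConfig(**mc)
        return cfg

    def validate(self) -> None:
        if not os.path.exists(self.fasta):
            raise FileNotFoundError(f"fasta not found: {self.fasta}")
        for p in (self.groups, self.annotations, self.alignment):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"input not found: {p}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"stages": {}, "outputs": {}, "summary": {}}

    def out(name: str) -> str:
        return os.path.join(config.out_dir, name)

    def register(path: str) -> None:
        manifest["outputs"][os.path.basename(path)] = _sha256(path)

    def stage(name: str, fn, *deps: str):
        for d in deps:
            if manifest["stages"].get(d) != "ok":
                manifest["stages"][name] = f"skipped (needs {d})"
                return None
        try:
            result = fn()
            manifest["stages"][name] = "ok"
            return result
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            log.error("stage %s failed: %s", name, exc)
            manifest["stages"][name] = f"failed: {exc}"
            return None

    state: dict = {}

    def load():
        genomes = io_formats.read_sequences(config.fasta)
        ref_id = config.reference or genomes[0].id
        if ref_id not in {g.id for g in genomes}:
            raise ValueError(f"reference {ref_id!r} not in FASTA")
        groups = io_formats.read_group_map(config.groups) if config.groups else None
        reference = next(g for g in genomes if g.id == ref_id)
        if config.annotations:
            reference = io_formats.read_annotations(config.annotations, reference)
            genomes = [reference if g.id == ref_id else g for g in genomes]
        state.update(genomes=genomes, reference=reference, groups=groups, ref_id=ref_id)
        manifest["summary"]["n_genomes"] = len(genomes)

    stage("load", load)

    def struct():
        rows = []
        canonical = []
        for g in state["genomes"]:
            st = structure.detect_quadripartite(g, min_ir_len=config.min_ir_len)
            canonical.append(structure.canonicalize(g, st))
            rows.append(
                dict(sample=g.id, length=st.genome_length, lsc=st.lsc_len,
                     ssc=st.ssc_len, ir=st.ir_len, rotation_offset=st.rotation_offset)
            )
        df = pd.DataFrame(rows)
        io_formats.write_tsv(df, out("structure.tsv"))
        register(out("structure.tsv"))
        state["canonical"] = canonical
        state["structure"] = canonical[[g.id for g in canonical].index(state["ref_id"])].structure
        ref_canon = next(g for g in canonical if g.id == state["ref_id"])
        state["reference"] = ref_canon
        if ref_canon.annotations:
            jc = structure.junction_report(ref_canon, ref_canon.structure)
            jrows = [
                dict(junction=j, gene=g, distance=d)
                for j, (g, d) in jc.junctions.items()
            ]
            io_formats.write_tsv(pd.DataFrame(jrows), out("junctions.tsv"))
            register(out("junctions.tsv"))

    stage("structure", struct, "load")

    def ssr_stage():
        cfg = ssr.SSRConfig.parse(config.ssr_thresholds)
        rows = []
        per_genome = {}
        for g in state["canonical"]:
            recs = ssr.scan_ssrs(g, cfg)
            recs = ssr.assign_regions(recs, g.structure or state["structure"])
            per_genome[g.id] = recs
            rows.extend(
                dict(sample=g.id, start=r.start, end=r.end, motif=r.motif,
                     canonical_motif=r.canonical_motif, copies=r.copies,
                     motif_class=r.motif_class, region=r.region)
                for r in recs
            )
        io_formats.write_tsv(pd.DataFrame(rows), out("ssr.tsv"))
        register(out("ssr.tsv"))
        manifest["summary"]["n_ssr_reference"] = len(per_genome[state["ref_id"]])
        state["ssr"] = per_genome

    stage("ssr", ssr_stage, "structure")

    def align_stage():
        if config.alignment:
            ids, rows = io_formats.read_aligned_fasta(config.alignment)
            aln = comparative.MultipleAlignment.from_aligned(ids, rows, state["ref_id"])
        else:
            aln = comparative.align_plastomes(state["canonical"], state["ref_id"])
        state["aln"] = aln

    stage("align", align_stage, "structure")

    def variants_stage():
        aln = state["aln"]
        variants = comparative.call_variants(aln)
        if state["reference"].annotations:
            variants = comparative.classify_regions(variants, state["reference"])
        sample_ids = [i for i in aln.ids]
        io_formats.write_vcf(variants, state["reference"], sample_ids, out("variants.vcf"))
        register(out("variants.vcf"))
        manifest["summary"]["n_snps"] = sum(1 for v in variants if v.kind == "SNP")
        manifest["summary"]["n_indels"] = sum(1 for v in variants if v.kind == "InDel")
        state["variants"] = variants
        if state["groups"]:
            diags = comparative.diagnostic_variants(variants, state["groups"])
            state["diagnostics"] = diags
            io_formats.write_tsv(
                pd.DataFrame(
                    [
                        dict(pos=d.variant.ref_pos, kind=d.variant.kind,
                             ref=d.variant.ref_allele,
                             alts=",".join(d.variant.alt_alleles),
                             region=d.variant.region, locus=d.variant.locus_label,
                             category=d.category,
                             partition="|".join(",".join(c) for c in d.partition))
                        for d in diags
                    ]
                ),
                out("diagnostics.tsv"),
            )
            register(out("diagnostics.tsv"))
            manifest["summary"]["n_diagnostic"] = len(diags)

    stage("variants", variants_stage, "align")

    def pi_stage():
        aln = state["aln"]
        cfg = diversity.DiversityConfig(window=config.pi_window, step=config.pi_step)
        profile = diversity.sliding_pi(aln, cfg)
        io_formats.write_pi_bed(profile, state["ref_id"], out("pi.bed"))
        register(out("pi.bed"))
        summary = diversity.summarize_pi(
            aln, profile, state["structure"], groups=state["groups"],
            reference=state["reference"] if state["reference"].annotations else None,
            hotspot_threshold=config.hotspot_threshold,
        )
        with open(out("pi_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        register(out("pi_summary.json"))
        manifest["summary"]["pi_regions"] = {
            k: v["mean"] for k, v in summary["regions"].items()
        }
        state["pi"] = summary

    stage("pi", pi_stage, "align")

    def marker_stage():
        if not state.get("diagnostics"):
            raise ValueError("marker design needs a groups file and diagnostics")
        aln, groups = state["aln"], state["groups"]
        genomes = state["canonical"]
        mcfg = config.marker_config
        indel_markers, failures = markers.design_indel_markers(
            aln, state["diagnostics"], genomes, groups, mcfg
        )
        rows = []
        validated = 0
        for m in indel_markers:
            res = markers.validate_marker(m, genomes, groups, mcfg)
            validated += bool(res.verdict)
            rows.append(
                dict(id=m.id, type="InDel", fwd=m.fwd.sequence, rev=m.rev.sequence,
                     locus=m.locus_label, category=m.category,
                     sizes=";".join(f"{g}={s}" for g, s in sorted(m.size_by_group.items())),
                     validated=res.verdict)
            )
        snp_diags = [
            d for d in state["diagnostics"]
            if d.variant.kind == "SNP" and len(set(d.allele_by_group.values())) == 2
        ]
        dcaps_all = []
        loci_with_designs = 0
        for d in snp_diags:
            if loci_with_designs >= config.max_dcaps_loci:
                break
            designs, dfail = markers.design_dcaps(aln, d, genomes, groups, config=mcfg)
            failures.extend(dfail)
            if designs:
                loci_with_designs += 1
            for dd in designs[:2]:  # keep the leading designs per locus
                res = markers.validate_marker(dd, genomes, groups, mcfg)
                validated += bool(res.verdict)
                dcaps_all.append(dd)
                rows.append(
                    dict(id=dd.id, type=dd.category, fwd=dd.fwd.sequence,
                         rev=dd.rev.sequence, locus=dd.locus_label,
                         category=dd.category,
                         sizes=";".join(
                             f"{a}={'/'.join(map(str, fr))}"
                             for a, fr in sorted(dd.fragments_by_allele.items())
                         ),
                         validated=res.verdict)
                )
        io_formats.write_tsv(pd.DataFrame(rows), out("markers.tsv"))
        register(out("markers.tsv"))
        manifest["summary"]["n_indel_markers"] = len(indel_markers)
        manifest["summary"]["n_dcaps_designs"] = len(dcaps_all)
        manifest["summary"]["n_markers_validated"] = validated
        manifest["summary"]["n_marker_failures"] = len(failures)
        state["markers"] = (indel_markers, dcaps_all)

    stage("markers", marker_stage, "variants")

    def phylo_stage():
        aln = state["aln"]
        if not state["reference"].annotations:
            raise ValueError("phylogeny needs reference annotations")
        sm = phylo.supermatrix_from_alignment(aln, state["reference"])
        outgroup = config.outgroup
        tree = phylo.nj_tree(
            sm, model=config.model, bootstrap_n=config.bootstrap,
            seed=config.seed, outgroup=outgroup,
        )
        io_formats.write_newick(tree.newick(), out("tree.nwk"))
        register(out("tree.nwk"))
        manifest["summary"]["n_shared_genes"] = len(sm.partitions)
        state["tree"] = tree

    stage("phylo", phylo_stage, "align")

    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
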