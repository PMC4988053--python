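"""Deterministic synthetic genomes-in-miniature with known truth networks.

The generator lays genes out at regularly spaced TSSs on one toy chromosome
per species, draws a random truth edge set over TF x genes, and then plants
exactly the genomic evidence the builders look for:

* for every truth edge, >=1 PWM hit inside the target's promoter window with
  p-value drawn log-uniformly below 1e-6 (so both the standard 1e-5 and the
  high-confidence 1e-6 thresholds retain it);
* ChIP peaks covering truth-edge windows for every TF;
* open-chromatin footprints (6-40 bp, hit fully contained) over a chosen
  fraction of the truth hits;
* decoy hits per gene — above-threshold hits inside windows, good hits in
  the inter-gene gaps outside every window, and hits of an unmapped matrix —
  none of which may create an edge.

With two species, orthologs are generated at a configurable one-to-many
rate and the second species' truth is the orthology transfer of the first,
so cross-species consistency holds by construction.  Identical parameters
and seed produce byte-identical output files.  Geometry and statistics only:
no sequences, no actual motif placement.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import GenerationError
from .genomic_io import GenomicFeature, MotifHit, MotifTFMap, TSSAnnotation, write_bed
from .netops import OrthologyMap, transfer_network
from .network_model import Evidence, Network, NetworkMetadata, write_network

__all__ = ["ScenarioParams", "SpeciesData", "ScenarioBundle",
           "simulate_scenario", "write_bundle"]

# geometry margins (bp): gap kept free of windows for out-of-window decoys,
# and the span inside a gene's slot reserved for extra TSSs
_MIN_GAP = 80
_MAX_TSS_SPAN = 3000
_DECOY_LEN = 10


@dataclass
class ScenarioParams:
    """Knobs of a synthetic scenario; identical params + seed => identical bytes."""

    seed: int = 0
    n_species: int = 1
    n_genes: int = 30
    n_tfs: int = 6
    chrom_length_bp: int = 0  # 0 = computed from gene count and spacing
    tss_spacing_bp: int = 20000
    window_bp: int = 5000
    edge_density: float = 0.15
    decoy_hit_rate: float = 1.0
    open_fraction: float = 1.0
    ortholog_one2many_rate: float = 0.1
    multi_tss_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.n_species not in (1, 2):
            raise ValueError("n_species must be 1 or 2")
        if self.n_genes < 2:
            raise ValueError("need at least two genes")
        if not (1 <= self.n_tfs <= self.n_genes):
            raise ValueError("need 1 <= n_tfs <= n_genes")
        for name in ("edge_density", "open_fraction",
                     "ortholog_one2many_rate", "multi_tss_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.decoy_hit_rate < 0:
            raise ValueError("decoy_hit_rate must be >= 0")

    @property
    def tss_span(self) -> int:
        return _MAX_TSS_SPAN if self.multi_tss_rate > 0 else 0

    def required_chrom_length(self) -> int:
        margin = self.window_bp + 1000
        return 2 * margin + self.n_genes * self.tss_spacing_bp

    def validate_geometry(self) -> None:
        gap = self.tss_spacing_bp - 2 * self.window_bp - self.tss_span
        if gap < _MIN_GAP:
            raise GenerationError(
                "promoter windows leave no inter-gene gap for out-of-window "
                "decoys; increase chrom_length_bp/tss_spacing_bp or shrink "
                f"window_bp (gap would be {gap} bp, need >= {_MIN_GAP})")
        if self.chrom_length_bp and self.chrom_length_bp < self.required_chrom_length():
            raise GenerationError(
                f"chrom_length_bp={self.chrom_length_bp} too small for "
                f"{self.n_genes} genes at {self.tss_spacing_bp} bp spacing; "
                f"increase chrom_length_bp to >= {self.required_chrom_length()}")


@dataclass
class SpeciesData:
    """All generated inputs and truth networks of one synthetic species."""

    species: str
    chrom: str
    genes: list[str]
    tfs: list[str]
    tss: list[TSSAnnotation]
    hits: list[MotifHit]
    motif_map: MotifTFMap
    chip_peaks: dict[str, list[GenomicFeature]]
    open_peaks: list[GenomicFeature]
    truth_tfbs: Network
    truth_open_chromatin: Network
    truth_chip: dict[str, Network]


@dataclass
class ScenarioBundle:
    params: ScenarioParams
    species: dict[str, SpeciesData]
    orthology: OrthologyMap | None = None


def _truth_network(network_id: str, species: str, edges: list[tuple[str, str]]) -> Network:
    net = Network(NetworkMetadata(network_id=network_id, species=species))
    for tf, tg in sorted(edges):
        net.add_evidence(tf, tg, Evidence(kind="Database", source_network_id=network_id))
    return net


def _place_species(
    params: ScenarioParams,
    rng: np.random.Generator,
    species: str,
    genes: list[str],
    tfs: list[str],
    truth_edges: list[tuple[str, str]],
) -> SpeciesData:
    """Generate geometry + evidence files realizing the given truth edges."""
    chrom = f"chr{species}"
    w = params.window_bp
    margin = w + 1000
    spacing = params.tss_spacing_bp
    span = params.tss_span

    # gene layout: one slot per gene; all TSSs of a gene stay inside
    # [base, base + span] so promoter windows of neighbours never touch
    tss_annotations: list[TSSAnnotation] = []
    gene_tss: dict[str, tuple[int, ...]] = {}
    gene_strand: dict[str, str] = {}
    slot_base: dict[str, int] = {}
    for i, gene in enumerate(genes):
        base = margin + i * spacing
        slot_base[gene] = base
        strand = "+" if rng.random() < 0.5 else "-"
        positions = {base}
        if span and rng.random() < params.multi_tss_rate:
            n_extra = int(rng.integers(1, 5))  # 2-5 TSSs total
            for _ in range(n_extra):
                positions.add(base + int(rng.integers(100, span)))
        gene_tss[gene] = tuple(sorted(positions))
        gene_strand[gene] = strand
        tss_annotations.append(TSSAnnotation(gene, chrom, strand, tuple(sorted(positions))))

    motif_map = MotifTFMap()
    for tf in tfs:
        motif_map.add(f"M_{tf}", tf)

    hits: list[MotifHit] = []
    open_peaks: list[GenomicFeature] = []
    chip_peaks: dict[str, list[GenomicFeature]] = {tf: [] for tf in tfs}
    truth_hits: list[tuple[MotifHit, tuple[str, str]]] = []
    hit_serial = 0

    def _plant_hit(matrix_id: str, lo: int, hi_excl: int, length: int,
                   p_value: float) -> MotifHit:
        nonlocal hit_serial
        hit_serial += 1
        start = int(rng.integers(lo, hi_excl))
        feat = GenomicFeature(chrom, start, start + length, "+",
                              round(float(rng.uniform(5, 25)), 3),
                              f"{matrix_id}:{hit_serial}", f"{species}_fimo")
        return MotifHit(feat, matrix_id, p_value, feat.score)

    for tf, tg in sorted(truth_edges):
        positions = gene_tss[tg]
        tss = int(positions[int(rng.integers(0, len(positions)))])
        n_hits = 1 + (1 if rng.random() < 0.3 else 0)
        for _ in range(n_hits):
            length = int(rng.integers(8, 16))
            p = float(10.0 ** rng.uniform(-9.0, -6.05))
            hit = _plant_hit(f"M_{tf}", tss - w + 1, tss + w - length, length, p)
            hits.append(hit)
            truth_hits.append((hit, (tf, tg)))
            if rng.random() < params.open_fraction:
                pad_l = int(rng.integers(1, max(2, (40 - length) // 2)))
                pad_r = int(rng.integers(1, max(2, (40 - length) // 2)))
                open_peaks.append(GenomicFeature(
                    chrom, hit.feature.start - pad_l, hit.feature.end + pad_r,
                    ".", None, f"oc:{hit.feature.feature_id}", f"{species}_oc"))
        # ChIP peak comfortably inside the window of the chosen TSS
        peak_len = int(rng.integers(200, 401))
        center = tss + int(rng.integers(-(w - 250), w - 250 + 1))
        chip_peaks[tf].append(GenomicFeature(
            chrom, max(0, center - peak_len // 2), center + peak_len // 2 + peak_len % 2,
            ".", round(float(rng.uniform(50, 1000)), 1),
            f"{tf}_{tg}_peak", f"{species}_chip_{tf}"))

    # decoys: must never create an edge
    all_matrices = sorted(motif_map.matrix_ids)
    for i, gene in enumerate(genes):
        for _ in range(int(rng.poisson(params.decoy_hit_rate))):
            kind = ("high_p", "outside", "unmapped")[int(rng.integers(0, 3))]
            positions = gene_tss[gene]
            tss = int(positions[int(rng.integers(0, len(positions)))])
            if kind == "outside":
                # inter-gene gap right of this gene's slot, clear of every window
                gap_lo = slot_base[gene] + span + w + 20
                gap_hi = slot_base[gene] + spacing - w - 20 - _DECOY_LEN
                if gap_hi <= gap_lo:  # guarded by validate_geometry
                    raise GenerationError(
                        "no inter-gene gap for decoy placement; increase "
                        "chrom_length_bp/tss_spacing_bp")
                matrix = all_matrices[int(rng.integers(0, len(all_matrices)))]
                hits.append(_plant_hit(matrix, gap_lo, gap_hi, _DECOY_LEN,
                                       float(10.0 ** rng.uniform(-9.0, -6.05))))
            elif kind == "high_p":
                matrix = all_matrices[int(rng.integers(0, len(all_matrices)))]
                hits.append(_plant_hit(matrix, tss - w + 1, tss + w - _DECOY_LEN,
                                       _DECOY_LEN, float(10.0 ** rng.uniform(-4.0, -2.0))))
            else:  # matrix with no TF mapping
                hits.append(_plant_hit("M_DECOY", tss - w + 1, tss + w - _DECOY_LEN,
                                       _DECOY_LEN, float(10.0 ** rng.uniform(-9.0, -6.05))))

    hits.sort(key=lambda h: (h.feature.start, h.feature.feature_id))
    open_peaks.sort(key=lambda p: (p.start, p.feature_id))

    # open-chromatin truth: edges whose >=1 truth hit lies fully inside a
    # peak (all generated peaks are footprint-eligible, 6-40 bp), so it is
    # exact for the footprint builder and equals the TFBS truth when every
    # hit is covered
    oc_edges = {
        edge for hit, edge in truth_hits
        if any(p.start <= hit.feature.start and hit.feature.end <= p.end
               for p in open_peaks)
    }

    return SpeciesData(
        species=species,
        chrom=chrom,
        genes=list(genes),
        tfs=list(tfs),
        tss=tss_annotations,
        hits=hits,
        motif_map=motif_map,
        chip_peaks=chip_peaks,
        open_peaks=open_peaks,
        truth_tfbs=_truth_network(f"{species}_truth_tfbs", species, truth_edges),
        truth_open_chromatin=_truth_network(f"{species}_truth_oc", species,
                                            sorted(oc_edges)),
        truth_chip={tf: _truth_network(f"{species}_truth_chip_{tf}", species,
                                       [(a, b) for a, b in truth_edges if a == tf])
                    for tf in tfs},
    )


def simulate_scenario(params: ScenarioParams) -> ScenarioBundle:
    """Generate a full scenario: inputs for every builder plus truth networks."""
    params.validate_geometry()
    rng = np.random.default_rng(params.seed)

    sp1 = "S1"
    genes1 = [f"{sp1}G{i:04d}" for i in range(1, params.n_genes + 1)]
    tfs1 = genes1[: params.n_tfs]
    truth_edges1 = [(tf, tg) for tf in tfs1 for tg in genes1
                    if rng.random() < params.edge_density]
    species = {sp1: _place_species(params, rng, sp1, genes1, tfs1, truth_edges1)}

    orthology: OrthologyMap | None = None
    if params.n_species == 2:
        sp2 = "S2"
        orthology = OrthologyMap(sp1, sp2)
        counter = 0
        ortho_of: dict[str, list[str]] = {}
        for gene in genes1:
            n_orth = 2 if rng.random() < params.ortholog_one2many_rate else 1
            targets = []
            for _ in range(n_orth):
                counter += 1
                targets.append(f"{sp2}G{counter:04d}")
            ortho_of[gene] = targets
            for t in targets:
                orthology.add(gene, t)
        genes2 = [t for gene in genes1 for t in ortho_of[gene]]
        tfs2 = [t for tf in tfs1 for t in ortho_of[tf]]
        transferred = transfer_network(species[sp1].truth_tfbs, orthology)
        truth_edges2 = sorted(transferred.edge_set())
        species[sp2] = _place_species(params, rng, sp2, genes2, tfs2, truth_edges2)

    return ScenarioBundle(params=params, species=species, orthology=orthology)


# ---------------------------------------------------------------------------
# serialization


def _write_fimo(hits: list[MotifHit], path: Path) -> None:
    cols = ["motif_id", "motif_alt_id", "sequence_name", "start", "stop",
            "strand", "score", "p-value", "q-value", "matched_sequence"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in hits:
            f = h.feature
            fh.write("\t".join([
                h.matrix_id, "", f.chrom, str(f.start + 1), str(f.end),
                f.strand, f"{h.score:g}", repr(h.p_value), "", "",
            ]) + "\n")


def _write_tss_bed(tss: list[TSSAnnotation], path: Path) -> None:
    with open(path, "w") as fh:
        for ann in tss:
            for pos in ann.tss_positions:
                fh.write(f"{ann.chrom}\t{pos}\t{pos + 1}\t{ann.gene_id}\t0\t{ann.strand}\n")


def _write_narrowpeak(peaks: list[GenomicFeature], path: Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            score = "0" if p.score is None else f"{p.score:g}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.feature_id}\t{score}"
                     f"\t{p.strand}\t0\t-1\t-1\t{p.length // 2}\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_bundle(bundle: ScenarioBundle, directory: str | Path) -> dict:
    """Write all scenario files in the package's external formats.

    Returns (and writes as ``manifest.json``) a manifest listing parameters,
    file paths, and truth-network checksums.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"params": asdict(bundle.params), "species": {}, "truth_checksums": {}}

    for sp, data in sorted(bundle.species.items()):
        files: dict[str, object] = {}
        tss_path = directory / f"{sp}_tss.bed"
        _write_tss_bed(data.tss, tss_path)
        files["tss"] = tss_path.name
        fimo_path = directory / f"{sp}_hits.fimo.tsv"
        _write_fimo(data.hits, fimo_path)
        files["fimo_hits"] = fimo_path.name
        map_path = directory / f"{sp}_motif_map.tsv"
        with open(map_path, "w") as fh:
            for matrix, tf in sorted(data.motif_map.pairs):
                fh.write(f"{matrix}\t{tf}\n")
        files["motif_map"] = map_path.name
        open_path = directory / f"{sp}_open_chromatin.bed"
        write_bed(data.open_peaks, open_path)
        files["open_chromatin"] = open_path.name
        files["chip"] = {}
        for tf in data.tfs:
            chip_path = directory / f"{sp}_chip_{tf}.narrowPeak"
            _write_narrowpeak(data.chip_peaks[tf], chip_path)
            files["chip"][tf] = chip_path.name
        files["truth"] = {}
        truth_nets = {"tfbs": data.truth_tfbs, "open_chromatin": data.truth_open_chromatin,
                      **{f"chip_{tf}": net for tf, net in sorted(data.truth_chip.items())}}
        for name, net in truth_nets.items():
            tpath = directory / f"{sp}_truth_{name}.tsv"
            write_network(net, tpath, "tsv")
            files["truth"][name] = tpath.name
            manifest["truth_checksums"][tpath.name] = _sha256(tpath)
        manifest["species"][sp] = files

    if bundle.orthology is not None:
        orth_path = directory / "orthology.tsv"
        with open(orth_path, "w") as fh:
            fh.write(f"#{bundle.orthology.species_from}\t{bundle.orthology.species_to}\n")
            for a, b in sorted(bundle.orthology.pairs):
                fh.write(f"{a}\t{b}\n")
        manifest["orthology"] = orth_path.name

    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
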