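"""Built-in synthetic study system: 33 jawed-vertebrate taxa, 7 clans.

The fixture species model mirrors the taxon structure of the amphibian
phylogenomic design the filter was built for: 18 ingroup amphibians
(8 Anura, 5 Caudata, 5 Gymnophiona) plus 15 outgroup vertebrates, with
Batrachia (Anura + Caudata) as the true ingroup topology.  Node ages are in
coalescent units and were chosen once to represent deep, well-separated
vertebrate divergences (long stems of roughly 3-7 units between the named
groups) over shallow within-group radiations (0.3-2.5 units) — i.e. visible
but moderate incomplete lineage sorting concentrated at short internal
branches, with group monophyly essentially safe under ILS alone.

Everything here is synthetic: it reproduces the *shape* of the study system
(taxon counts, group structure, clan definitions, family-size range), not
any real transcriptome data.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from . import clanfilter, simulate, treeio
from .clanfilter import ClanSet, GeneFamilyRecord
from .simulate import SimulationConfig, SpeciesModel, SpeciesNode
from .treeio import SpeciesMap

__all__ = [
    "ANURA",
    "CAUDATA",
    "GYMNOPHIONA",
    "OUTGROUPS",
    "default_species_model",
    "default_species_map",
    "default_clans",
    "generate_fixtures",
]

ANURA = (
    "Xenopus_tropicalis",
    "Nanorana_parkeri",
    "Craugastor_fitzingeri",
    "Hyla_arborea",
    "Espadarana_prosoblepon",
    "Rhinella_marina",
    "Allobates_femoralis",
    "Dendrobates_tinctorius",
)
CAUDATA = (
    "Hynobius_chinensis",
    "Ambystoma_mexicanum",
    "Ambystoma_tigrinum",
    "Notophthalmus_viridescens",
    "Pleurodeles_waltl",
)
GYMNOPHIONA = (
    "Rhinatrema_bivittatum",
    "Siphonops_annulatus",
    "Microcaecilia_unicolor",
    "Caecilia_tentaculata",
    "Typhlonectes_compressicauda",
)
MAMMALS = ("Ornithorhynchus_anatinus", "Loxodonta_africana", "Bos_taurus", "Homo_sapiens")
BIRDS = ("Gallus_gallus", "Taeniopygia_guttata")
REPTILES = ("Pelodiscus_sinensis", "Anolis_carolinensis", "Ophiophagus_hannah")
FISHES = (
    "Petromyzon_marinus",
    "Callorhinchus_milii",
    "Danio_rerio",
    "Takifugu_rubripes",
    "Latimeria_chalumnae",
    "Protopterus_annectens",
)
OUTGROUPS = MAMMALS + BIRDS + REPTILES + FISHES


def _leaf(name: str) -> SpeciesNode:
    return SpeciesNode(name=name, age=0.0)


def _node(age: float, *children: SpeciesNode) -> SpeciesNode:
    return SpeciesNode(name="", age=age, children=list(children))


def default_species_model(dup_spacing: float = 1.0) -> SpeciesModel:
    """The 33-taxon fixture species tree (ages in coalescent units)."""
    anura = _node(
        1.8,
        _leaf("Xenopus_tropicalis"),
        _node(
            1.5,
            _leaf("Nanorana_parkeri"),
            _node(
                1.2,
                _leaf("Craugastor_fitzingeri"),
                _node(
                    1.0,
                    _leaf("Hyla_arborea"),
                    _node(
                        0.8,
                        _leaf("Espadarana_prosoblepon"),
                        _node(
                            0.6,
                            _leaf("Rhinella_marina"),
                            _node(0.4, _leaf("Allobates_femoralis"), _leaf("Dendrobates_tinctorius")),
                        ),
                    ),
                ),
            ),
        ),
    )
    caudata = _node(
        1.5,
        _leaf("Hynobius_chinensis"),
        _node(
            1.0,
            _node(0.3, _leaf("Ambystoma_mexicanum"), _leaf("Ambystoma_tigrinum")),
            _node(0.6, _leaf("Notophthalmus_viridescens"), _leaf("Pleurodeles_waltl")),
        ),
    )
    gymnophiona = _node(
        1.5,
        _leaf("Rhinatrema_bivittatum"),
        _node(
            1.0,
            _node(0.6, _leaf("Siphonops_annulatus"), _leaf("Microcaecilia_unicolor")),
            _node(0.7, _leaf("Caecilia_tentaculata"), _leaf("Typhlonectes_compressicauda")),
        ),
    )
    lissamphibia = _node(8.0, _node(6.0, anura, caudata), gymnophiona)
    mammals = _node(
        2.5,
        _leaf("Ornithorhynchus_anatinus"),
        _node(1.6, _leaf("Loxodonta_africana"), _node(1.0, _leaf("Bos_taurus"), _leaf("Homo_sapiens"))),
    )
    sauropsids = _node(
        6.0,
        _node(
            4.0,
            _node(0.5, _leaf("Gallus_gallus"), _leaf("Taeniopygia_guttata")),
            _leaf("Pelodiscus_sinensis"),
        ),
        _node(2.0, _leaf("Anolis_carolinensis"), _leaf("Ophiophagus_hannah")),
    )
    amniota = _node(10.0, mammals, sauropsids)
    tetrapoda = _node(12.0, lissamphibia, amniota)
    sarcopterygii = _node(17.0, _node(16.0, tetrapoda, _leaf("Protopterus_annectens")), _leaf("Latimeria_chalumnae"))
    actinopterygii = _node(5.0, _leaf("Danio_rerio"), _leaf("Takifugu_rubripes"))
    osteichthyes = _node(18.0, sarcopterygii, actinopterygii)
    gnathostomata = _node(20.0, osteichthyes, _leaf("Callorhinchus_milii"))
    root = _node(24.0, gnathostomata, _leaf("Petromyzon_marinus"))
    return SpeciesModel(root=root, dup_spacing=dup_spacing)


def default_species_map() -> SpeciesMap:
    """Identity leaf mapping plus the Anura/Caudata/Gymnophiona/outgroup groups."""
    groups: Dict[str, str] = {}
    groups.update({t: "Anura" for t in ANURA})
    groups.update({t: "Caudata" for t in CAUDATA})
    groups.update({t: "Gymnophiona" for t in GYMNOPHIONA})
    groups.update({t: "outgroup" for t in OUTGROUPS})
    return SpeciesMap.identity(ANURA + CAUDATA + GYMNOPHIONA + OUTGROUPS, groups)


def default_clans() -> ClanSet:
    """The seven incontestable jawed-vertebrate clans."""
    tetrapods = ANURA + CAUDATA + GYMNOPHIONA + MAMMALS + BIRDS + REPTILES
    return ClanSet.from_pairs(
        [
            ("mammals", MAMMALS),
            ("birds", BIRDS),
            ("birds_reptiles", BIRDS + REPTILES),
            ("frogs", ANURA),
            ("salamanders", CAUDATA),
            ("caecilians", GYMNOPHIONA),
            ("tetrapods", tetrapods),
        ]
    )


def _clean_family_set(
    model: SpeciesModel,
    config: SimulationConfig,
    species_map: SpeciesMap,
    rng: np.random.Generator,
) -> List[GeneFamilyRecord]:
    """Ortholog families that follow the species tree exactly (no conflict)."""
    records = []
    for i in range(config.n_families):
        taxa = simulate.sample_occupancy(config, model.taxa, rng)
        gtree = simulate._species_restriction(model.root, frozenset(taxa))
        records.append(
            GeneFamilyRecord(
                family_id=f"clean{i + 1:05d}",
                tree=simulate._gene_tree_to_unrooted(gtree),
                species_map=species_map,
            )
        )
    return records


def generate_fixtures(seed: int, out_dir, n_families: int = 100) -> Dict[str, str]:
    """Write the full fixture set and a truth manifest; returns file paths.

    Emits the species model (newick), species/group/clan TSVs, and three
    gene-family tree sets — clean orthologs, ILS-only, duplication +
    late loss — each with per-family truth (supported triplet topology and
    clan verdict) recorded in ``manifest.json``.  Byte-identical for a
    fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = default_species_model()
    species_map = default_species_map()
    clans = default_clans()

    paths = {
        "model": str(out / "species_model.nwk"),
        "species": str(out / "species.tsv"),
        "groups": str(out / "groups.tsv"),
        "clans": str(out / "clans.tsv"),
        "clean": str(out / "trees_clean.tsv"),
        "ils": str(out / "trees_ils.tsv"),
        "duploss": str(out / "trees_duploss.tsv"),
        "manifest": str(out / "manifest.json"),
    }
    Path(paths["model"]).write_text(model.to_newick() + "\n")
    with open(paths["species"], "w") as fh:
        for taxon in model.taxa:
            fh.write(f"{taxon}\t{taxon}\n")
    with open(paths["groups"], "w") as fh:
        for taxon in model.taxa:
            fh.write(f"{taxon}\t{species_map.group_of(taxon)}\n")
    with open(paths["clans"], "w") as fh:
        fh.write("# clan_name\tcomma-separated taxa\n")
        for name, taxa in clans:
            fh.write(f"{name}\t{','.join(sorted(taxa))}\n")

    base = SimulationConfig(n_families=n_families, n_replicates=1, seed=seed)
    streams = np.random.SeedSequence(seed).spawn(3)
    sets = {
        "clean": _clean_family_set(model, base, species_map, np.random.default_rng(streams[0])),
        "ils": simulate.simulate_family_set(
            model,
            SimulationConfig(n_families=n_families, n_replicates=1, seed=seed, mode="ils_only"),
            np.random.default_rng(streams[1]),
            species_map,
            prefix="ils",
        ),
        "duploss": simulate.simulate_family_set(
            model,
            SimulationConfig(n_families=n_families, n_replicates=1, seed=seed, mode="dup_late_loss"),
            np.random.default_rng(streams[2]),
            species_map,
            prefix="dup",
        ),
    }
    manifest: Dict[str, dict] = {"seed": seed, "n_families": n_families, "families": {}}
    ingroups = ("Anura", "Caudata", "Gymnophiona")
    for set_name, records in sets.items():
        with open(paths[set_name], "w") as fh:
            for rec in records:
                fh.write(f"{rec.family_id}\t{rec.tree.to_newick()}\n")
                report = clanfilter.check_family(rec, clans)
                groups_present = {species_map.group_of(t) for t in rec.taxa}
                topology = None
                if all(g in groups_present for g in (*ingroups, "outgroup")):
                    pair = treeio.classify_triplet(rec.tree, ingroups, "outgroup", species_map)
                    topology = "+".join(sorted(pair)) if pair else "unresolved"
                manifest["families"][rec.family_id] = {
                    "set": set_name,
                    "n_taxa": len(rec.taxa),
                    "verdict": report.verdict,
                    "violated_clans": report.violated_clans,
                    "triplet_topology": topology,
                }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
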