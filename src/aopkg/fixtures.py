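"""Zero-download test data.

``build_case_study`` constructs, deterministically and with no I/O, a small
knowledge graph for the clofibrate → PPARA → hepatic fibrosis case:

* the five-node answer path clofibrate — PPARA — "cellular response to
  lipid" (GO:0071396) — CCL2 — hepatic fibrosis, with the first hop carried
  by seven parallel curated/text-mined edges across six predicates (CTD's
  ``increases_expression_of`` with 12 supporting publications, DrugCentral,
  Drug Mechanism Database, Human Metabolome Database, Binding Database, and
  two Text Mining Provider edges with 3 and 2 publications);
* Hetionet ``actively_involved_in`` / ``actively_involves`` edges on hops
  2-3 and a DisGeNET-via-Pharos ``genetically_associated_with`` edge on
  hop 4;
* six additional curated filler edges (two per hop on hops 2-4) so the CCL2
  answer carries 16 curated edges in total — these are synthesized
  reconstructions, attributed to the source ``fixture:unenumerated``, not
  assertions of any real knowledge source;
* 11 further gene/protein nodes joining GO:0071396 to hepatic fibrosis, and
  30 further biological-process nodes joining PPARA to CCL2;
* a literature corpus whose posting lists give co-occurrence counts of 4
  for (clofibrate, PPARA), 8 for (PPARA, hepatic fibrosis), and nonzero
  counts for exactly four more bound-node pairs, so the CCL2 answer gains
  exactly six co-occurrence edges.

Publication identifiers are synthetic tokens (``PMID:FIX…``, ``PMID:OC…``);
no PubMed access is needed or implied.

``random_instance`` builds seeded random graphs with a planted query path
for property tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .biolink_model import default_hierarchies
from .errors import ParameterError
from .kg_store import Edge, KnowledgeGraph, Node, save_kg
from .normalization import SynonymClique, SynonymCliqueTable, save_clique_table
from .omnicorp import CorpusIndex, save_corpus
from .query_model import QueryGraph, builtin_template, serialize_query

CLOFIBRATE = "PUBCHEM.COMPOUND:2796"
PPARA = "NCBIGene:5465"
CELLULAR_RESPONSE_TO_LIPID = "GO:0071396"
CCL2 = "NCBIGene:6347"
HEPATIC_FIBROSIS = "HP:0001395"

FILLER_SOURCE = "fixture:unenumerated"

#: (abbreviation, NCBI CURIE) — intermediary genes/proteins beyond CCL2
ADDITIONAL_GENES = (
    ("IL-6", "NCBIGene:3569"),
    ("TGFB1", "NCBIGene:7040"),
    ("COL1A1", "NCBIGene:1277"),
    ("CD14", "NCBIGene:929"),
    ("HDAC2", "NCBIGene:3066"),
    ("NPC1", "NCBIGene:4864"),
    ("TNFRSF1B", "NCBIGene:7133"),
    ("ABCB4", "NCBIGene:5244"),
    ("PLAU", "NCBIGene:5328"),
    ("IL-12A", "NCBIGene:3592"),
    ("STAT1", "NCBIGene:6772"),
)

#: (label, GO CURIE) — intermediary processes/activities beyond GO:0071396.
#: Two labels each appear under two distinct GO ids; node identity is by
#: CURIE, the duplicate labels are kept as synonyms.
ADDITIONAL_PROCESSES = (
    ("protein binding", "GO:0005515"),
    ("response to hypoxia", "GO:0001666"),
    ("response to lipid", "GO:0033993"),
    ("response to insulin", "GO:0032868"),
    ("response to wounding", "GO:0009611"),
    ("regulation of inflammatory response", "GO:0050727"),
    ("regulation of cell adhesion", "GO:0030155"),
    ("response to ethanol", "GO:0045471"),
    ("response to steroid hormone", "GO:0048545"),
    ("circulatory system development", "GO:0072359"),
    ("regulation of leukocyte cell-cell adhesion", "GO:1903037"),
    ("cellular response to steroid hormone stimulus", "GO:0071383"),
    ("response to peptide", "GO:1901652"),
    ("cellular response to organic cyclic compound", "GO:0071407"),
    ("response to organic cyclic compound", "GO:0014070"),
    ("response to nutrient levels", "GO:0031667"),
    ("regulation of defense response", "GO:0031347"),
    ("anatomical structure formation involved in morphogenesis", "GO:0048646"),
    ("cellular response to hormone stimulus", "GO:0032870"),
    ("negative regulation of developmental process", "GO:0051093"),
    ("response to oxygen levels", "GO:0070482"),
    ("response to organonitrogen compound", "GO:0010243"),
    ("regulation of response to wounding", "GO:1903034"),
    ("regulation of response to external stimulus", "GO:0032101"),
    ("response to decreased oxygen levels", "GO:0036293"),
    ("response to peptide hormone", "GO:0043434"),
    ("regulation of response to external stimulus", "GO:0032102"),
    ("regulation of cell adhesion", "GO:0022407"),
    ("animal organ morphogenesis", "GO:0009887"),
    ("response to nutrient", "GO:0007584"),
)

#: pairwise literature co-occurrence counts among the five answer-path nodes;
#: pairs not listed never co-occur.
COOCCURRENCE_COUNTS = {
    (CLOFIBRATE, PPARA): 4,
    (PPARA, HEPATIC_FIBROSIS): 8,
    (PPARA, CELLULAR_RESPONSE_TO_LIPID): 3,
    (CELLULAR_RESPONSE_TO_LIPID, CCL2): 2,
    (CCL2, HEPATIC_FIBROSIS): 5,
    (CLOFIBRATE, HEPATIC_FIBROSIS): 2,
}

_CTD_PUBLICATION_NOTE = (
    "Clofibrate, a peroxisome-proliferator, enhances reverse cholesterol "
    "transport through cytochrome P450 activation and oxysterol generation"
)


@dataclass
class CaseStudyBundle:
    kg: KnowledgeGraph
    cliques: SynonymCliqueTable
    corpus: CorpusIndex
    queries: dict[str, QueryGraph]


def _pubs(start: int, count: int) -> frozenset[str]:
    return frozenset(f"PMID:FIX{start + i:05d}" for i in range(count))


def build_case_study() -> CaseStudyBundle:
    """Deterministically assemble the case-study bundle."""
    cats, preds = default_hierarchies()
    g = KnowledgeGraph(cats, preds)

    g.add_node(Node(CLOFIBRATE, "clofibrate", ("ChemicalEntity",)))
    g.add_node(Node(PPARA, "PPARA", ("Gene", "Protein")))
    g.add_node(Node(CELLULAR_RESPONSE_TO_LIPID, "cellular response to lipid", ("BiologicalProcess",)))
    g.add_node(Node(CCL2, "CCL2", ("Gene",)))
    g.add_node(Node(HEPATIC_FIBROSIS, "hepatic fibrosis", ("PhenotypicFeature",)))
    for name, curie in ADDITIONAL_GENES:
        g.add_node(Node(curie, name, ("Gene",)))
    for label, curie in ADDITIONAL_PROCESSES:
        category = "MolecularActivity" if curie == "GO:0005515" else "BiologicalProcess"
        g.add_node(Node(curie, label, (category,)))

    def edge(eid, s, p, o, source, pubs=frozenset(), aggregators=(), qualifiers=None):
        g.add_edge(
            Edge(eid, s, o, p, source, tuple(aggregators), frozenset(pubs), dict(qualifiers or {}))
        )

    # hop 1: seven parallel curated/text-mined clofibrate -> PPARA edges
    edge("hop1-01-ctd", CLOFIBRATE, "increases_expression_of", PPARA,
         "infores:ctd", _pubs(1, 12), qualifiers={"publication_note": _CTD_PUBLICATION_NOTE})
    edge("hop1-02-drugcentral", CLOFIBRATE, "increases_activity_of", PPARA,
         "infores:drugcentral", _pubs(13, 1))
    edge("hop1-03-drugmechdb", CLOFIBRATE, "increases_response_to", PPARA,
         "infores:drugmechdb", _pubs(14, 1))
    edge("hop1-04-hmdb", CLOFIBRATE, "decreases_response_to", PPARA,
         "infores:hmdb", _pubs(15, 1))
    edge("hop1-05-bindingdb", CLOFIBRATE, "affects", PPARA,
         "infores:bindingdb", _pubs(16, 1))
    edge("hop1-06-tmp", CLOFIBRATE, "affects", PPARA,
         "infores:text-mining-provider", _pubs(17, 3))
    edge("hop1-07-tmp", CLOFIBRATE, "related_to", PPARA,
         "infores:text-mining-provider", _pubs(20, 2))

    # hop 2: Hetionet plus two filler edges
    edge("hop2-01-hetionet", PPARA, "actively_involved_in", CELLULAR_RESPONSE_TO_LIPID,
         "infores:hetionet")
    edge("hop2-02-filler", PPARA, "participates_in", CELLULAR_RESPONSE_TO_LIPID,
         FILLER_SOURCE, _pubs(22, 1))
    edge("hop2-03-filler", PPARA, "related_to", CELLULAR_RESPONSE_TO_LIPID,
         FILLER_SOURCE, _pubs(23, 1))

    # hop 3: Hetionet plus two filler edges
    edge("hop3-01-hetionet", CELLULAR_RESPONSE_TO_LIPID, "actively_involves", CCL2,
         "infores:hetionet")
    edge("hop3-02-filler", CELLULAR_RESPONSE_TO_LIPID, "has_participant", CCL2,
         FILLER_SOURCE, _pubs(24, 1))
    edge("hop3-03-filler", CELLULAR_RESPONSE_TO_LIPID, "related_to", CCL2,
         FILLER_SOURCE, _pubs(25, 1))

    # hop 4: DisGeNET via Pharos plus two filler edges
    edge("hop4-01-disgenet", CCL2, "genetically_associated_with", HEPATIC_FIBROSIS,
         "infores:disgenet", _pubs(26, 1), aggregators=("infores:pharos",))
    edge("hop4-02-filler", CCL2, "associated_with", HEPATIC_FIBROSIS,
         FILLER_SOURCE, _pubs(27, 1))
    edge("hop4-03-filler", CCL2, "related_to", HEPATIC_FIBROSIS,
         FILLER_SOURCE, _pubs(28, 1))

    # further gene answers: GO:0071396 -> gene -> hepatic fibrosis
    for i, (name, curie) in enumerate(ADDITIONAL_GENES):
        edge(f"gene-{name}-01-hetionet", CELLULAR_RESPONSE_TO_LIPID, "actively_involves",
             curie, "infores:hetionet")
        edge(f"gene-{name}-02-disgenet", curie, "genetically_associated_with",
             HEPATIC_FIBROSIS, "infores:disgenet", _pubs(100 + 3 * i, 1 + i % 3),
             aggregators=("infores:pharos",))

    # further process answers: PPARA -> process -> CCL2
    for label, curie in ADDITIONAL_PROCESSES:
        suffix = curie.split(":")[1]
        edge(f"proc-{suffix}-01-hetionet", PPARA, "actively_involved_in", curie,
             "infores:hetionet")
        edge(f"proc-{suffix}-02-hetionet", curie, "actively_involves", CCL2,
             "infores:hetionet")

    cliques = _case_study_cliques(g)
    corpus = _case_study_corpus()
    queries = {
        "fig1b_full": builtin_template(
            "aop_chem_gene_process_gene_phenotype",
            {"chemical": CLOFIBRATE, "phenotype": HEPATIC_FIBROSIS},
        ),
        "table1_genes": builtin_template(
            "aop_chem_gene_process_gene_phenotype",
            {"chemical": CLOFIBRATE, "gene1": PPARA,
             "process": CELLULAR_RESPONSE_TO_LIPID, "phenotype": HEPATIC_FIBROSIS},
        ),
        "table2_processes": builtin_template(
            "aop_chem_gene_process_gene_phenotype",
            {"chemical": CLOFIBRATE, "gene1": PPARA,
             "gene2": CCL2, "phenotype": HEPATIC_FIBROSIS},
        ),
    }
    return CaseStudyBundle(g, cliques, corpus, queries)


def _case_study_cliques(g: KnowledgeGraph) -> SynonymCliqueTable:
    aliased = {
        CLOFIBRATE: (("CHEBI:3750", "DRUGBANK:DB00636"), ("clofibrate",)),
        PPARA: (("UniProtKB:Q07869",),
                ("PPARA", "peroxisome proliferator activated receptor alpha")),
        CCL2: (("UniProtKB:P13500",), ("CCL2", "monocyte chemoattractant protein 1")),
        HEPATIC_FIBROSIS: (("UMLS:C0239946",), ("hepatic fibrosis",)),
    }
    cliques = []
    for curie in sorted(g.nodes):
        node = g.nodes[curie]
        extra_members, extra_labels = aliased.get(curie, ((), ()))
        cliques.append(
            SynonymClique(
                preferred_curie=curie,
                preferred_label=node.name,
                member_curies=frozenset((curie, *extra_members)),
                labels=frozenset((node.name, *extra_labels)),
            )
        )
    return SynonymCliqueTable(cliques)


def _case_study_corpus() -> CorpusIndex:
    """Posting lists realizing COOCCURRENCE_COUNTS exactly: each pair shares
    a dedicated block of publications mentioned by that pair alone, so every
    other intersection is empty by construction."""
    postings: dict[str, set[str]] = {}
    serial = 0
    for (a, b), count in sorted(COOCCURRENCE_COUNTS.items()):
        for _ in range(count):
            serial += 1
            pub = f"PMID:OC{serial:05d}"
            postings.setdefault(a, set()).add(pub)
            postings.setdefault(b, set()).add(pub)
    return CorpusIndex({c: frozenset(p) for c, p in postings.items()})


def write_bundle(bundle: CaseStudyBundle, out_dir) -> None:
    """Write the bundle in the standard layout: nodes.tsv, edges.tsv,
    cliques.tsv, corpus.tsv, and queries/<name>.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_kg(bundle.kg, out / "nodes.tsv", out / "edges.tsv")
    save_clique_table(bundle.cliques, out / "cliques.tsv")
    save_corpus(bundle.corpus, out / "corpus.tsv")
    qdir = out / "queries"
    qdir.mkdir(exist_ok=True)
    for name in sorted(bundle.queries):
        (qdir / f"{name}.json").write_text(serialize_query(bundle.queries[name]) + "\n")


# -- random instances for property tests -------------------------------------

_NODE_CATEGORIES = (
    "ChemicalEntity", "Gene", "Protein", "BiologicalProcess",
    "MolecularActivity", "Disease", "PhenotypicFeature", "Cell",
)
_QUERY_PREDICATES = (
    "related_to", "related_to", "affects", "associated_with",
    "actively_involved_in", "actively_involves", "interacts_with",
    "genetically_associated_with",
)

MAX_RANDOM_NODES = 50


def random_instance(
    seed: int,
    n_nodes: int = 20,
    n_hops: int = 3,
    n_extra_edges: int = 30,
    n_publications: int = 40,
) -> tuple[KnowledgeGraph, QueryGraph, CorpusIndex]:
    """A seeded random KG with a planted path guaranteeing >= 1 match.

    The query path's nodes are randomly pinned or categorical; each planted
    edge's predicate is drawn from the descendants of the query predicate
    and stored in an admissible orientation, so the planted binding always
    matches.  Extra edges and postings are uniform noise.
    """
    if not (1 <= n_nodes <= MAX_RANDOM_NODES):
        raise ParameterError(f"n_nodes must be in [1, {MAX_RANDOM_NODES}], got {n_nodes}")
    if not (0 <= n_hops <= 6) or n_hops >= n_nodes:
        raise ParameterError(f"n_hops must be in [0, 6] and < n_nodes, got {n_hops}")
    rng = random.Random(seed)
    cats, preds = default_hierarchies()
    g = KnowledgeGraph(cats, preds)
    curies = [f"FIXR:{i:04d}" for i in range(n_nodes)]
    for curie in curies:
        n_cats = rng.choice((1, 1, 2))
        node_cats = tuple(rng.sample(_NODE_CATEGORIES, n_cats))
        g.add_node(Node(curie, f"entity {curie}", node_cats))

    planted = rng.sample(curies, n_hops + 1)
    from .query_model import QueryEdge, QueryNode  # local to avoid cycle at import

    qnodes, qedges = [], []
    for i, curie in enumerate(planted):
        if rng.random() < 0.4:
            qnodes.append(QueryNode(f"n{i}", pinned_curie=curie))
        else:
            leaf = rng.choice(g.nodes[curie].categories)
            category = rng.choice(sorted(cats.ancestors(leaf) - {"NamedThing"}))
            qnodes.append(QueryNode(f"n{i}", category=category))
    eid = 0
    for u, v in zip(planted, planted[1:]):
        qpred = rng.choice(_QUERY_PREDICATES)
        stored = rng.choice(sorted(preds.descendants(qpred)))
        if preds.is_symmetric(qpred) and rng.random() < 0.5:
            s, o = v, u
        elif not preds.is_symmetric(qpred) and preds.inverse(stored) and rng.random() < 0.3:
            s, o, stored = v, u, preds.inverse(stored)
        else:
            s, o = u, v
        g.add_edge(Edge(f"planted-{eid:03d}", s, o, stored, "source:random",
                        publications=_random_pubs(rng, n_publications)))
        if rng.random() < 0.5:
            qedges.append(QueryEdge(f"e{eid}", f"n{eid}", f"n{eid + 1}", qpred))
        else:  # flip the query edge too when the predicate allows it
            if preds.is_symmetric(qpred):
                qedges.append(QueryEdge(f"e{eid}", f"n{eid + 1}", f"n{eid}", qpred))
            else:
                qedges.append(QueryEdge(f"e{eid}", f"n{eid}", f"n{eid + 1}", qpred))
        eid += 1

    all_preds = sorted(preds.members)
    for i in range(n_extra_edges):
        s, o = rng.choice(curies), rng.choice(curies)
        if s == o:
            continue
        g.add_edge(Edge(f"noise-{i:03d}", s, o, rng.choice(all_preds), "source:random",
                        publications=_random_pubs(rng, n_publications)))

    postings = {
        curie: frozenset(
            f"PMID:R{p:04d}" for p in rng.sample(range(n_publications), rng.randint(0, 6))
        )
        for curie in curies
    }
    return g, QueryGraph(tuple(qnodes), tuple(qedges)), CorpusIndex(postings)


def _random_pubs(rng: random.Random, n_publications: int) -> frozenset[str]:
    return frozenset(
        f"PMID:R{p:04d}" for p in rng.sample(range(n_publications), rng.randint(0, 4))
    )
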