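"""Bundled toy lexical-semantic resource.

A small, fully synthetic stand-in for a real wordnet-style taxonomy and a
real embedding corpus, covering exactly the four fluency task categories
(animals, jobs, sports, fruits).  Each category is a subtree whose leaves are
words grouped into semantic clusters (pets, farm animals, citrus fruits ...),
so cluster-structured retrieval walks over it produce realistic
sequential/cumulative relatedness profiles.  Matched 16-dimensional
embeddings place each word near its cluster centroid, so the taxonomy and
embedding backends agree on coarse structure but not numerically.

The resource is generated in code (deterministically) rather than shipped as
data files; :func:`write_toy_resource` materializes the on-disk formats.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from .semantic_resource import EmbeddingTable, Taxonomy, save_embeddings, save_taxonomy

# category -> cluster -> leaf words.  One synset per leaf word plus internal
# cluster/category/root nodes.
CATEGORY_CLUSTERS: dict[str, dict[str, list[str]]] = {
    "animals": {
        "pets": ["dog", "cat", "hamster", "rabbit", "parrot", "goldfish"],
        "farm": ["cow", "pig", "sheep", "goat", "horse", "donkey"],
        "wild": ["lion", "tiger", "elephant", "giraffe", "wolf", "bear"],
        "birds": ["eagle", "sparrow", "owl", "stork", "penguin"],
        "water": ["dolphin", "shark", "trout", "seal", "octopus"],
    },
    "jobs": {
        "medical": ["doctor", "nurse", "surgeon", "pharmacist", "midwife"],
        "trades": ["carpenter", "plumber", "electrician", "mason", "roofer"],
        "education": ["teacher", "professor", "librarian", "tutor"],
        "service": ["waiter", "cook", "cashier", "driver", "barber"],
        "creative": ["painter", "musician", "architect", "photographer"],
    },
    "sports": {
        "ball": ["soccer", "tennis", "basketball", "handball", "volleyball"],
        "water_sports": ["swimming", "rowing", "surfing", "diving"],
        "winter": ["skiing", "skating", "biathlon", "curling"],
        "athletics": ["running", "hurdles", "javelin", "marathon"],
        "combat": ["judo", "boxing", "fencing"],
    },
    "fruits": {
        "citrus": ["orange", "lemon", "grapefruit", "mandarin"],
        "berries": ["strawberry", "blueberry", "raspberry", "currant"],
        "tropical": ["banana", "mango", "pineapple", "papaya", "kiwi"],
        "orchard": ["apple", "pear", "cherry", "plum", "apricot"],
    },
}

TASK_WORDS: dict[str, list[str]] = {
    cat: [w for cluster in clusters.values() for w in cluster]
    for cat, clusters in CATEGORY_CLUSTERS.items()
}

_EMBED_SEED = 20210325  # fixed: the toy resource is a constant, not a simulation
_EMBED_DIM = 16


def build_toy_taxonomy() -> Taxonomy:
    """Four category subtrees under a common root; one synset per word."""
    g = nx.Graph()
    g.add_node("root")
    lexicon: dict[str, frozenset[str]] = {}
    for category, clusters in CATEGORY_CLUSTERS.items():
        cat_node = f"cat:{category}"
        g.add_edge("root", cat_node)
        for cluster, words in clusters.items():
            cl_node = f"cl:{category}:{cluster}"
            g.add_edge(cat_node, cl_node)
            for word in words:
                syn = f"syn:{word}"
                g.add_edge(cl_node, syn)
                lexicon[word] = frozenset({syn})
    return Taxonomy(graph=g, lexicon=lexicon)


def build_toy_embeddings() -> EmbeddingTable:
    """Matched 16-dim vectors: category + cluster directions + word noise."""
    rng = np.random.default_rng(_EMBED_SEED)
    vectors: dict[str, np.ndarray] = {}
    for category, clusters in CATEGORY_CLUSTERS.items():
        cat_dir = rng.normal(size=_EMBED_DIM)
        cat_dir /= np.linalg.norm(cat_dir)
        for words in clusters.values():
            cl_dir = rng.normal(size=_EMBED_DIM)
            cl_dir /= np.linalg.norm(cl_dir)
            for word in words:
                noise = rng.normal(scale=0.25, size=_EMBED_DIM)
                vec = 1.0 * cat_dir + 0.6 * cl_dir + noise
                vectors[word] = vec / np.linalg.norm(vec)
    return EmbeddingTable(vectors=vectors, dim=_EMBED_DIM)


def write_toy_resource(directory: str | Path) -> None:
    """Materialize the toy taxonomy (TSVs) and embeddings (word2vec text)."""
    directory = Path(directory)
    save_taxonomy(build_toy_taxonomy(), directory / "taxonomy")
    save_embeddings(build_toy_embeddings(), directory / "embeddings.vec")
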