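"""Pluggable lexical-semantic backends for word relatedness.

Two measures are implemented, mirroring the two families of semantic systems
used to score fluency output:

* **Taxonomy path similarity** over an undirected synset graph (a wordnet-style
  lexical-semantic net).  For synsets ``s1, s2``::

      sim(s1, s2) = (MAXSHORTESTPATH - length(s1, s2)) / MAXSHORTESTPATH

  where ``length`` counts edges on the shortest path and ``MAXSHORTESTPATH``
  is the longest finite shortest path anywhere in the graph (the graph
  "diameter" over reachable pairs).  Identical synsets score 1; a pair at the
  diameter scores 0.  Words mapping to several synsets resolve to the synset
  pair with the *closest* relatedness; a word absent from the lexicon makes
  the pair undefined (``None``) and the caller drops it.

* **Embedding cosine similarity** over a word-vector table (word2vec text
  format).  Undefined (``None``) when either word has no vector.  Cosine may
  be negative for arbitrary embeddings; values are used as-is downstream
  since only relative ordering matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np


@dataclass
class Taxonomy:
    """Undirected synset graph with a word -> synsets lexicon.

    ``max_shortest_path`` is the maximum over all *finite* pairwise
    shortest-path lengths; for disconnected graphs, cross-component pairs are
    undefined rather than infinite.
    """

    graph: nx.Graph
    lexicon: dict[str, frozenset[str]]
    max_shortest_path: int = field(init=False)
    _dist: dict[str, dict[str, int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for word, synsets in self.lexicon.items():
            for s in synsets:
                if s not in self.graph:
                    raise ValueError(f"lexicon entry {word!r} -> unknown synset {s!r}")
        # All-pairs BFS; cached because every similarity query needs it.
        self._dist = {s: d for s, d in nx.all_pairs_shortest_path_length(self.graph)}
        self.max_shortest_path = max(
            (d for row in self._dist.values() for d in row.values()), default=0
        )

    @property
    def synsets(self) -> set[str]:
        return set(self.graph.nodes)

    def path_similarity(self, s1: str, s2: str) -> float | None:
        """Path similarity in [0, 1]; None for mutually unreachable synsets."""
        if s1 not in self.graph or s2 not in self.graph:
            raise KeyError(f"synset not in taxonomy: {s1 if s1 not in self.graph else s2}")
        length = self._dist[s1].get(s2)
        if length is None:
            return None
        if self.max_shortest_path == 0:
            return 1.0  # single-node degenerate taxonomy: only s1 == s2 reachable
        return (self.max_shortest_path - length) / self.max_shortest_path

    def word_similarity(self, w1: str, w2: str) -> float | None:
        """Max path similarity over all synset pairs; None if a word is unlisted."""
        syn1 = self.lexicon.get(w1)
        syn2 = self.lexicon.get(w2)
        if not syn1 or not syn2:
            return None
        best: float | None = None
        for a in syn1:
            for b in syn2:
                sim = self.path_similarity(a, b)
                if sim is not None and (best is None or sim > best):
                    best = sim
        return best

    def __contains__(self, word: str) -> bool:
        return word in self.lexicon


@dataclass
class EmbeddingTable:
    """Word -> dense vector table of fixed dimension."""

    vectors: dict[str, np.ndarray]
    dim: int

    def __post_init__(self) -> None:
        for w, v in self.vectors.items():
            if v.shape != (self.dim,):
                raise ValueError(f"vector for {w!r} has shape {v.shape}, expected ({self.dim},)")
            if not np.any(v):
                raise ValueError(f"zero vector for {w!r}")

    def word_similarity(self, w1: str, w2: str) -> float | None:
        """Cosine similarity; None when either word has no vector."""
        v1 = self.vectors.get(w1)
        v2 = self.vectors.get(w2)
        if v1 is None or v2 is None:
            return None
        return float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))

    def __contains__(self, word: str) -> bool:
        return word in self.vectors


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------

def load_taxonomy(
    synsets_path: str | Path,
    edges_path: str | Path,
    lexicon_path: str | Path,
) -> Taxonomy:
    """Load a taxonomy from TSV files.

    ``synsets.tsv``: ``id`` (optional second gloss column); ``edges.tsv``:
    ``id1  id2``; ``lexicon.tsv``: ``word  synset_id`` (one row per sense).
    Edge endpoints must be declared synsets.
    """
    graph = nx.Graph()
    for line in _data_lines(synsets_path):
        parts = line.split("\t")
        graph.add_node(parts[0])
    for line in _data_lines(edges_path):
        a, b = line.split("\t")[:2]
        for endpoint in (a, b):
            if endpoint not in graph:
                raise ValueError(f"{edges_path}: edge endpoint {endpoint!r} is not a declared synset")
        graph.add_edge(a, b)
    lexicon: dict[str, set[str]] = {}
    for line in _data_lines(lexicon_path):
        word, synset = line.split("\t")[:2]
        lexicon.setdefault(word, set()).add(synset)
    return Taxonomy(graph=graph, lexicon={w: frozenset(s) for w, s in lexicon.items()})


def _data_lines(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line and not line.startswith("#"):
                yield line


def load_embeddings(path: str | Path) -> EmbeddingTable:
    """Load word vectors in word2vec text format ("N d" header, then rows)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: expected 'N d' word2vec header, got {header!r}")
        n, dim = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        for lineno, raw in enumerate(fh, start=2):
            parts = raw.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(
                    f"{path} line {lineno}: expected word + {dim} floats, got {len(parts)} fields"
                )
            vectors[parts[0]] = np.asarray([float(x) for x in parts[1:]], dtype=float)
    if len(vectors) != n:
        raise ValueError(f"{path}: header declared {n} words, found {len(vectors)}")
    return EmbeddingTable(vectors=vectors, dim=dim)


def save_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vectors)} {table.dim}\n")
        for word, vec in table.vectors.items():
            fh.write(word + " " + " ".join(f"{x:.6f}" for x in vec) + "\n")


def save_taxonomy(tax: Taxonomy, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "synsets.tsv", "w", encoding="utf-8") as fh:
        for node in tax.graph.nodes:
            fh.write(f"{node}\n")
    with open(directory / "edges.tsv", "w", encoding="utf-8") as fh:
        for a, b in tax.graph.edges:
            fh.write(f"{a}\t{b}\n")
    with open(directory / "lexicon.tsv", "w", encoding="utf-8") as fh:
        for word in sorted(tax.lexicon):
            for synset in sorted(tax.lexicon[word]):
                fh.write(f"{word}\t{synset}\n")
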