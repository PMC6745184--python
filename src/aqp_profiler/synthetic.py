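"""Ground-truth synthetic fixtures for every pipeline stage.

Generated proteins mimic the canonical aquaporin architecture: six
hydrophobic transmembrane (TM) segments joined by hydrophilic loops, the
two N-P-X motifs planted in loops B and E, and the ar/R filter, Froger
and SDP residues planted at fixed, layout-consistent positions.  Anchors
of the same subfamily share a background sequence (classes diverge by a
small mutation rate); different subfamilies have independent backgrounds,
so inter-subfamily distances exceed intra-subfamily ones by construction.
Background composition is uniform over reduced alphabets chosen for
hydropathy contrast, with proline and asparagine excluded from loop
backgrounds so the only N-P-X occurrences are the planted motifs; no
claim of biological realism is made beyond that structure.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import pi

import numpy as np

from .quant import CtTable, SwellingSeries, sphere_geometry, VW_WATER
from .seqio import FEATURE_KEYS, ProteinSequence, ReferenceAnchor, SUBFAMILIES

import pandas as pd

HYDROPHOBIC = "ILVF"
# no P/N (planted motifs stay the only N-P-X) and no A (keeps loop
# hydropathy firmly below the TM threshold)
LOOP_RESIDUES = "STQGEDKRHY"

SEQ_LENGTH = 250
#: six TM segments, 1-based inclusive, 25 residues each
DEFAULT_TM_LAYOUT = tuple((20 + 40 * k, 44 + 40 * k) for k in range(6))

#: planted feature positions (1-based), all inside loops of the layout
#: except H2/H5 which sit mid-helix as in real AQPs
DEFAULT_FEATURE_POSITIONS = {
    "NPA_LB": 85, "NPA_LE": 205,
    "H2": 70, "H5": 190, "LE1": 209, "LE2": 211,
    "P1": 213, "P2": 214, "P3": 215, "P4": 216, "P5": 217,
    "SDP1": 46, "SDP2": 48, "SDP3": 90, "SDP4": 92, "SDP5": 126,
    "SDP6": 128, "SDP7": 166, "SDP8": 168, "SDP9": 219,
}

#: family-typical planted residues per subfamily (NPA variants, ar/R,
#: Froger, SDP) following the published family profiles
SUBFAMILY_FEATURES = {
    "PIP": {"npa_lb": "NPA", "npa_le": "NPA", "arr": ("F", "H", "T", "R"),
            "froger": ("Q", "S", "A", "F", "W"),
            "sdp": ("H", "P", "F", "F", "L", "P", "G", "G", "N")},
    "TIP": {"npa_lb": "NPA", "npa_le": "NPA", "arr": ("H", "I", "G", "R"),
            "froger": ("T", "S", "A", "Y", "W"),
            "sdp": ("T", "L", "T", "V", "A", "S", "H", "P", "A")},
    "NIP": {"npa_lb": "NPA", "npa_le": "NPA", "arr": ("W", "V", "A", "R"),
            "froger": ("F", "S", "A", "Y", "L"),
            "sdp": ("F", "T", "F", "T", "A", "D", "L", "E", "T")},
    "SIP": {"npa_lb": "NPT", "npa_le": "NPA", "arr": ("I", "V", "P", "I"),
            "froger": ("I", "A", "A", "Y", "W"),
            "sdp": ("A", "A", "A", "A", "A", "A", "A", "A", "A")},
}

PANEL_CLASSES = {"PIP": ("PIP1", "PIP2"), "TIP": ("TIP1", "TIP2"),
                 "NIP": ("NIP1", "NIP4"), "SIP": ("SIP1", "SIP2")}


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one synthetic query with fully known feature truth."""

    subfamily: str = "PIP"
    class_label: str = "PIP1"
    tm_layout: tuple[tuple[int, int], ...] = DEFAULT_TM_LAYOUT
    npa_lb: str = ""
    npa_le: str = ""
    arr: tuple[str, ...] = ()
    froger: tuple[str, ...] = ()
    sdp: tuple[str, ...] = ()
    flank_mutation_rate: float = 0.0
    seed: int = 0
    panel_seed: int = 0

    def resolved(self) -> "PlantSpec":
        """Fill empty feature fields with the subfamily defaults."""
        defaults = SUBFAMILY_FEATURES[self.subfamily]
        return replace(
            self,
            npa_lb=self.npa_lb or defaults["npa_lb"],
            npa_le=self.npa_le or defaults["npa_le"],
            arr=tuple(self.arr) or defaults["arr"],
            froger=tuple(self.froger) or defaults["froger"],
            sdp=tuple(self.sdp) or defaults["sdp"],
        )


@dataclass(frozen=True)
class QueryTruth:
    """Planted ground truth: every feature's position and residue."""

    tm_layout: tuple[tuple[int, int], ...]
    feature_positions: dict[str, int]
    feature_residues: dict[str, str]  # per feature key; NPA keys hold trimers


def _planted_cells(spec: PlantSpec) -> dict[int, str]:
    """1-based position -> residue for all planted features; validates layout."""
    if not 0 <= spec.flank_mutation_rate <= 1:
        raise ValueError("flank_mutation_rate must be in [0, 1]")
    pos = DEFAULT_FEATURE_POSITIONS
    cells: dict[int, str] = {}

    def plant(p: int, residue: str, name: str):
        if p in cells and cells[p] != residue:
            raise ValueError(f"infeasible layout: {name} overlaps position {p}")
        cells[p] = residue

    for offset, res in enumerate(spec.npa_lb):
        plant(pos["NPA_LB"] + offset, res, "NPA_LB")
    for offset, res in enumerate(spec.npa_le):
        plant(pos["NPA_LE"] + offset, res, "NPA_LE")
    for key, res in zip(("H2", "H5", "LE1", "LE2"), spec.arr):
        plant(pos[key], res, key)
    for k, res in enumerate(spec.froger, start=1):
        plant(pos[f"P{k}"], res, f"P{k}")
    for k, res in enumerate(spec.sdp, start=1):
        plant(pos[f"SDP{k}"], res, f"SDP{k}")

    loops = _loop_mask(spec.tm_layout)
    for key in ("NPA_LB", "NPA_LE"):
        if not loops[pos[key] - 1]:
            raise ValueError(f"infeasible layout: {key} not in a loop")
    return cells


def _loop_mask(tm_layout) -> np.ndarray:
    mask = np.ones(SEQ_LENGTH, dtype=bool)
    for start, end in tm_layout:
        mask[start - 1:end] = False
    return mask


def _background(rng: np.random.Generator, tm_layout) -> np.ndarray:
    """Random background: hydrophobic inside TMs, hydrophilic in loops.

    Each TM segment is a shuffled balanced I/L/V/F multiset rather than an
    iid draw, so every planted helix has the same strongly hydrophobic
    composition and the six-helix architecture survives windowed
    hydropathy at any seed.
    """
    seq = np.empty(SEQ_LENGTH, dtype="<U1")
    loops = _loop_mask(tm_layout)
    seq[loops] = rng.choice(list(LOOP_RESIDUES), size=int(loops.sum()))
    for start, end in tm_layout:
        length = end - start + 1
        balanced = list((HYDROPHOBIC * (length // len(HYDROPHOBIC) + 1))[:length])
        seq[start - 1:end] = rng.permutation(balanced)
    return seq


def _subfamily_base(subfamily: str, panel_seed: int) -> np.ndarray:
    rng = np.random.default_rng([panel_seed, 1000 + SUBFAMILIES.index(subfamily)])
    return _background(rng, DEFAULT_TM_LAYOUT)


def _mutate(seq: np.ndarray, rate: float, protected: set[int],
            rng: np.random.Generator, tm_layout) -> np.ndarray:
    """Mutate non-protected positions in place-preserving alphabet classes."""
    out = seq.copy()
    loops = _loop_mask(tm_layout)
    for i in range(SEQ_LENGTH):
        if (i + 1) in protected or rng.random() >= rate:
            continue
        alphabet = LOOP_RESIDUES if loops[i] else HYDROPHOBIC
        choices = [c for c in alphabet if c != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def make_reference_panel(seed: int = 0) -> list[ReferenceAnchor]:
    """Two anchors per subfamily with internally consistent planted features.

    Deterministic per seed; the panel validates against the anchor-table
    reader and is the default classification panel for synthetic runs.
    """
    anchors = []
    for subfamily in SUBFAMILIES:
        base = _subfamily_base(subfamily, seed)
        for class_idx, class_label in enumerate(PANEL_CLASSES[subfamily]):
            spec = PlantSpec(subfamily=subfamily, class_label=class_label,
                             panel_seed=seed).resolved()
            cells = _planted_cells(spec)
            rng = np.random.default_rng(
                [seed, 2000 + SUBFAMILIES.index(subfamily), class_idx])
            seq = _mutate(base, 0.08, set(cells), rng, spec.tm_layout)
            for p, res in cells.items():
                seq[p - 1] = res
            anchors.append(ReferenceAnchor(
                sequence=ProteinSequence(id=f"Ref{class_label};1",
                                         residues="".join(seq)),
                subfamily=subfamily, class_label=class_label,
                feature_positions=dict(DEFAULT_FEATURE_POSITIONS)))
    return anchors


def make_query(spec: PlantSpec) -> tuple[ProteinSequence, QueryTruth]:
    """A synthetic query realizing all planted features exactly.

    The sequence derives from its subfamily's background (shared with the
    reference panel of the same ``panel_seed``), non-feature positions are
    mutated at ``flank_mutation_rate``, and the features are written last,
    so they survive any mutation rate.
    """
    spec = spec.resolved()
    cells = _planted_cells(spec)
    base = _subfamily_base(spec.subfamily, spec.panel_seed)
    if spec.class_label in PANEL_CLASSES[spec.subfamily]:
        # replay the panel's class-divergence step so the query is nearest
        # its own class anchor
        class_idx = PANEL_CLASSES[spec.subfamily].index(spec.class_label)
        class_rng = np.random.default_rng(
            [spec.panel_seed, 2000 + SUBFAMILIES.index(spec.subfamily), class_idx])
        base = _mutate(base, 0.08, set(cells), class_rng, spec.tm_layout)
    rng = np.random.default_rng([spec.panel_seed, 3000 + spec.seed])
    seq = _mutate(base, spec.flank_mutation_rate, set(cells), rng, spec.tm_layout)
    for p, res in cells.items():
        seq[p - 1] = res
    residues = "".join(seq)
    truth = QueryTruth(
        tm_layout=spec.tm_layout,
        feature_positions=dict(DEFAULT_FEATURE_POSITIONS),
        feature_residues={
            "NPA_LB": spec.npa_lb, "NPA_LE": spec.npa_le,
            **{k: r for k, r in zip(("H2", "H5", "LE1", "LE2"), spec.arr)},
            **{f"P{k}": r for k, r in enumerate(spec.froger, start=1)},
            **{f"SDP{k}": r for k, r in enumerate(spec.sdp, start=1)},
        },
    )
    # hyphen, not underscore: newick readers treat unquoted underscores as spaces
    qid = f"syn{spec.class_label}-s{spec.seed}"
    return ProteinSequence(id=qid, residues=residues), truth


# ---------------------------------------------------------------------------
# Oocyte swelling simulation

def make_swelling_series(pf_true: float,
                         radius_cm: float = 0.065,
                         osm_in: float = 2.0e-4,
                         osm_out: float = 0.4e-4,
                         noise_sd: float = 0.0,
                         dt_s: float = 0.5,
                         duration_min: float = 10.0,
                         sample_every_min: float = 0.5,
                         seed: int = 0,
                         oocyte_id: str = "oocyte",
                         group: str = "construct") -> SwellingSeries:
    """Forward-Euler integration of the spherical swelling model.

    dV/dt = Pf * S(V) * Vw * (osm_in - osm_out) with S the sphere surface
    at volume V.  Defaults emulate a 1.3 mm oocyte moved into a 5-fold
    diluted bath (osmolalities in mol/cm^3, so a 160 mOsm gradient).
    Gaussian noise of ``noise_sd`` (fraction of the initial area) is added
    to the sampled cross-sectional areas; deterministic per seed.
    """
    if pf_true < 0 or dt_s <= 0:
        raise ValueError("pf_true must be >= 0 and dt_s positive")
    rng = np.random.default_rng(seed)
    area0 = pi * radius_cm ** 2
    v, _ = sphere_geometry(area0)
    gradient = osm_in - osm_out

    times = np.arange(0.0, duration_min + 1e-9, sample_every_min)
    sample_steps = np.round(times * 60.0 / dt_s).astype(int)
    volumes = []
    step = 0
    for target in sample_steps:
        while step < target:
            _, s = _sphere_from_volume(v)
            v = v + dt_s * pf_true * s * VW_WATER * gradient
            step += 1
        volumes.append(v)
    radii = (np.array(volumes) * 3.0 / (4.0 * pi)) ** (1.0 / 3.0)
    areas = pi * radii ** 2
    if noise_sd > 0:
        areas = areas + rng.normal(0.0, noise_sd * area0, size=areas.shape)
        areas = np.maximum(areas, 0.05 * area0)
    return SwellingSeries(oocyte_id=oocyte_id, times=tuple(times),
                          areas=tuple(areas), osm_in=osm_in, osm_out=osm_out,
                          group=group)


def _sphere_from_volume(v: float) -> tuple[float, float]:
    r = (v * 3.0 / (4.0 * pi)) ** (1.0 / 3.0)
    return v, 4.0 * pi * r ** 2


# ---------------------------------------------------------------------------
# qPCR tables

def make_ct_table(true_folds: dict[str, dict[str, float]],
                  ref_ct: float = 20.0,
                  noise_sd: float = 0.0,
                  bio_replicates: int = 3,
                  tech_replicates: int = 3,
                  seed: int = 0,
                  reference_gene: str = "actin") -> CtTable:
    """Replicated Ct table with known relative abundances.

    ``true_folds[gene][sample]`` is the gene's abundance relative to the
    reference, so Ct(gene) = ref_ct - log2(abundance) plus biological
    (sd = ``noise_sd``) and technical (sd = ``noise_sd``/2) Gaussian
    noise.  Three biological x three technical replicates by default.
    """
    rng = np.random.default_rng(seed)
    samples = sorted({s for folds in true_folds.values() for s in folds})
    rows = []
    for gene in [reference_gene] + sorted(true_folds):
        for sample in samples:
            if gene != reference_gene and sample not in true_folds[gene]:
                continue
            abundance = 1.0 if gene == reference_gene else true_folds[gene][sample]
            if abundance <= 0:
                raise ValueError("abundances must be positive")
            true_ct = ref_ct - np.log2(abundance)
            for bio in range(1, bio_replicates + 1):
                bio_noise = rng.normal(0.0, noise_sd) if noise_sd else 0.0
                for tech in range(1, tech_replicates + 1):
                    tech_noise = rng.normal(0.0, noise_sd / 2) if noise_sd else 0.0
                    rows.append({"gene": gene, "sample": sample, "bio_rep": bio,
                                 "tech_rep": tech,
                                 "ct": true_ct + bio_noise + tech_noise})
    return CtTable(pd.DataFrame(rows), reference_gene)


# ---------------------------------------------------------------------------
# Additive distance fixtures

def make_additive_matrix(n_taxa: int, seed: int = 0):
    """A random tree metric plus the generating topology's splits.

    Builds a random unrooted binary tree with branch lengths U(0.1, 1.0),
    returns its leaf-to-leaf path-length distance matrix (additive by
    construction) and the set of non-trivial splits, canonicalized as the
    leaf side not containing the first taxon.
    """
    from skbio import DistanceMatrix

    if n_taxa < 3:
        raise ValueError("need at least three taxa")
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n_taxa)]
    adj: dict[object, dict[object, float]] = {}

    def connect(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def disconnect(u, v):
        del adj[u][v]
        del adj[v][u]

    center = "i0"
    for leaf in labels[:3]:
        connect(center, leaf, rng.uniform(0.1, 1.0))
    next_internal = 1
    for leaf in labels[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if str(u) < str(v)]
        u, v = edges[rng.integers(len(edges))]
        w = adj[u][v]
        mid = f"i{next_internal}"
        next_internal += 1
        frac = rng.uniform(0.2, 0.8)
        disconnect(u, v)
        connect(u, mid, w * frac)
        connect(mid, v, w * (1 - frac))
        connect(mid, leaf, rng.uniform(0.1, 1.0))

    def path_lengths(src):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, w in adj[node].items():
                if nb not in dist:
                    dist[nb] = dist[node] + w
                    stack.append(nb)
        return dist

    d = np.zeros((n_taxa, n_taxa))
    for i, leaf in enumerate(labels):
        dist = path_lengths(leaf)
        for j, other in enumerate(labels):
            d[i, j] = dist[other]
    d = 0.5 * (d + d.T)  # remove float asymmetry from traversal order

    splits = set()
    leaf_set = set(labels)
    for u in adj:
        for v in adj[u]:
            if str(u) < str(v):
                side = _reachable(adj, u, without=v) & leaf_set
                if 2 <= len(side) <= n_taxa - 2:
                    canon = frozenset(side if labels[0] not in side
                                      else leaf_set - side)
                    splits.add(canon)
    return DistanceMatrix(d, labels), splits


def _reachable(adj, start, without):
    seen = {start, without}
    stack = [start]
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    seen.discard(without)
    return seen
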