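"""Graph isomorphism network (GIN) encoder for molecular graphs.

Each layer updates node states as

    h_v^(k) = MLP^(k)( (1 + eps_k) * h_v^(k-1)
                       + sum_{u in N(v)} ( h_u^(k-1) + proj(e_{uv}) ) )

— sum aggregation over incoming directed edges with the edge feature
projected to the node width and added to the source-node message.  The
whole-graph readout concatenates, over depths k = 0..K, the sum of node
states at depth k, and a final linear map projects that vector to the
shared embedding width (default 100) used by the fusion stage.

Sum aggregation is the point: unlike mean or max pooling it is injective
on feature multisets, so structurally different neighborhoods (e.g. one
neighbor vs. two identical neighbors) receive different aggregates.

The encoder's weights are fixed at initialization from the random seed
and never trained: it acts as a deterministic random-feature structural
encoder, which is all the downstream fusion stage requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .chem import MolecularGraph, featurize, parse_smiles

SHARED_DIM = 100


@dataclass
class GinLayerParams:
    """Parameters of one GIN layer; ``None`` weights mean an identity MLP."""

    epsilon: float = 0.0
    w1: np.ndarray | None = None
    b1: np.ndarray | None = None
    w2: np.ndarray | None = None
    b2: np.ndarray | None = None
    edge_proj: np.ndarray | None = None  # f_edge -> node width


def gin_layer(node_feats: np.ndarray, graph: MolecularGraph,
              params: GinLayerParams, edge_feats: np.ndarray | None = None) -> np.ndarray:
    """One round of sum-aggregated message passing (see module docstring)."""
    agg = np.zeros_like(node_feats)
    if graph.directed_edges:
        edges = np.asarray(graph.directed_edges, dtype=np.intp)
        src, dst = edges[:, 0], edges[:, 1]
        messages = node_feats[src]
        if edge_feats is not None:
            if params.edge_proj is not None:
                edge_feats = edge_feats @ params.edge_proj
            if edge_feats.shape != messages.shape:
                raise ValueError(
                    f"edge feature shape {edge_feats.shape} does not match "
                    f"message shape {messages.shape}")
            messages = messages + edge_feats
        np.add.at(agg, dst, messages)
    pre = (1.0 + params.epsilon) * node_feats + agg
    if params.w1 is None:
        return pre
    hidden = np.maximum(pre @ params.w1 + params.b1, 0.0)
    return hidden @ params.w2 + params.b2


def readout(per_layer_node_feats: list[np.ndarray], graph: MolecularGraph) -> np.ndarray:
    """Concat-over-depth of per-depth node sums (permutation invariant)."""
    if not per_layer_node_feats:
        raise ValueError("readout requires at least the depth-0 node features")
    return np.concatenate([m.sum(axis=0) for m in per_layer_node_feats])


class GINEncoder(TransformerMixin, BaseEstimator):
    """Molecular-graph → fixed-width embedding transformer.

    Parameters
    ----------
    hidden_dim : node state width inside the message-passing stack.
    n_layers : number of GIN layers K (readout concatenates K+1 depths).
    out_dim : width of the final graph embedding (shared fusion width).
    feature_scheme : atom/bond featurization scheme name.
    random_state : seed for the fixed random weights.
    """

    def __init__(self, hidden_dim: int = 32, n_layers: int = 5, out_dim: int = SHARED_DIM,
                 feature_scheme: str = "minimal", random_state: int = 0):
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.out_dim = out_dim
        self.feature_scheme = feature_scheme
        self.random_state = random_state

    # -- fitting --------------------------------------------------------
    def _as_graph(self, item) -> MolecularGraph:
        if isinstance(item, MolecularGraph):
            if item.node_features is None:
                featurize(item, self.feature_scheme)
            return item
        return featurize(parse_smiles(str(item)), self.feature_scheme)

    def fit(self, X, y=None):
        """Initialize the fixed random weights; X is a list of graphs or SMILES."""
        graphs = [self._as_graph(g) for g in X]
        if not graphs:
            raise ValueError("need at least one graph to infer feature dimensions")
        f_node = graphs[0].node_features.shape[1]
        f_edge = graphs[0].edge_features.shape[1]
        rng = np.random.default_rng(self.random_state)

        def glorot(fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=(fan_in, fan_out))

        h = self.hidden_dim
        self.input_proj_ = glorot(f_node, h)
        self.layers_ = []
        for _ in range(self.n_layers):
            self.layers_.append(GinLayerParams(
                epsilon=0.0,
                w1=glorot(h, h), b1=np.zeros(h),
                w2=glorot(h, h), b2=np.zeros(h),
                edge_proj=glorot(f_edge, h),
            ))
        self.readout_proj_ = glorot((self.n_layers + 1) * h, self.out_dim)
        self.n_features_in_ = f_node
        return self

    # -- encoding -------------------------------------------------------
    def encode_graph(self, graph: MolecularGraph) -> np.ndarray:
        """Embed one featurized molecular graph as an ``out_dim`` vector."""
        if graph.node_features is None:
            raise ValueError("graph must be featurized before encoding")
        h = graph.node_features @ self.input_proj_
        states = [h]
        for params in self.layers_:
            h = gin_layer(h, graph, params, edge_feats=graph.edge_features)
            states.append(h)
        return readout(states, graph) @ self.readout_proj_

    def transform(self, X) -> np.ndarray:
        return np.vstack([self.encode_graph(self._as_graph(g)) for g in X])


def encode_drug(graph: MolecularGraph, encoder: GINEncoder) -> np.ndarray:
    """Embed one drug's molecular graph with a fitted :class:`GINEncoder`."""
    return encoder.encode_graph(graph)
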