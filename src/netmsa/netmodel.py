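"""NEAT-style recurrent network phenotypes: genomes, lesion masks, evaluation.

A network is described genetically as a list of node genes (bias, response,
activation and aggregation function names) and connection genes (weighted,
directed, with an ``enabled`` flag; disabled connections are pseudogenes that
pass zero).  A lesion is a severed connection: node lesions are realised by
severing the node's incoming/outgoing connections.

The recurrent update is synchronous with a one-step delay: at time ``t`` every
non-input node reads the ``t-1`` activations of its non-input sources and the
time-``t`` values of its input sources, so self-loops are well defined and the
update order is irrelevant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "ConfigurationError",
    "CapacityError",
    "NodeGene",
    "ConnectionGene",
    "Genome",
    "LesionMask",
    "EMPTY_MASK",
    "NetworkState",
    "ActivityTrace",
    "register_activation",
    "register_aggregation",
    "prune_disabled",
    "mask_connections",
    "node_lesion_mask",
    "step",
    "run",
    "CompiledNetwork",
]


class ValidationError(ValueError):
    """An input violates a structural precondition."""


class ConfigurationError(ValidationError):
    """An activation/aggregation name is not registered."""


class CapacityError(RuntimeError):
    """A problem size exceeds a configured exact-computation limit."""


# ---------------------------------------------------------------------------
# Activation / aggregation registries
# ---------------------------------------------------------------------------

#: Clamp on sigmoid/tanh pre-activations; avoids overflow in exp.
Z_CLAMP = 60.0


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -Z_CLAMP, Z_CLAMP)))


def _identity(z: np.ndarray) -> np.ndarray:
    return z


def _tanh(z: np.ndarray) -> np.ndarray:
    return np.tanh(np.clip(z, -Z_CLAMP, Z_CLAMP))


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sigmoid": _sigmoid,
    "identity": _identity,
    "tanh": _tanh,
    "relu": _relu,
}


def _agg_sum(terms: np.ndarray) -> np.ndarray:
    return terms.sum(axis=0)


def _agg_max(terms: np.ndarray) -> np.ndarray:
    return terms.max(axis=0)


def _agg_min(terms: np.ndarray) -> np.ndarray:
    return terms.min(axis=0)


def _agg_maxabs(terms: np.ndarray) -> np.ndarray:
    # sign-preserving maximum by magnitude
    idx = np.abs(terms).argmax(axis=0)
    return np.take_along_axis(terms, idx[None, ...], axis=0)[0]


def _agg_mean(terms: np.ndarray) -> np.ndarray:
    return terms.mean(axis=0)


AGGREGATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sum": _agg_sum,
    "max": _agg_max,
    "min": _agg_min,
    "maxabs": _agg_maxabs,
    "mean": _agg_mean,
}


def register_activation(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register a vectorised activation function under ``name``."""
    ACTIVATIONS[name] = fn


def register_aggregation(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register an aggregation; ``fn`` reduces axis 0 of a (k, ...) array."""
    AGGREGATIONS[name] = fn


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

_ROLES = ("input", "hidden", "output")


@dataclass(frozen=True)
class NodeGene:
    """One node: identity, role and its transfer-function genes.

    By convention input nodes carry negative ids and non-input nodes
    non-negative ids; this is validated only as far as roles are consistent
    with usage, not enforced on the sign of the id.  Input nodes carry the
    stimulus value directly — their activation/aggregation are never applied.
    """

    id: int
    role: str
    activation: str = "sigmoid"
    aggregation: str = "sum"
    bias: float = 0.0
    response: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValidationError(f"unknown node role {self.role!r}")
        if self.role != "input":
            if self.activation not in ACTIVATIONS:
                raise ConfigurationError(
                    f"unregistered activation {self.activation!r} on node {self.id}"
                )
            if self.aggregation not in AGGREGATIONS:
                raise ConfigurationError(
                    f"unregistered aggregation {self.aggregation!r} on node {self.id}"
                )


@dataclass(frozen=True)
class ConnectionGene:
    """A weighted directed connection; disabled connections pass zero."""

    source: int
    target: int
    weight: float
    enabled: bool = True

    @property
    def key(self) -> tuple[int, int]:
        return (self.source, self.target)


@dataclass
class Genome:
    """A lesionable network description (node genes + connection genes)."""

    nodes: list[NodeGene]
    connections: list[ConnectionGene]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate node ids")
        if not self.input_ids or not self.output_ids:
            raise ValidationError("genome needs at least one input and one output node")
        known = set(ids)
        keys = set()
        for c in self.connections:
            if c.source not in known or c.target not in known:
                raise ValidationError(f"connection {c.key} references unknown node")
            if c.key in keys:
                raise ValidationError(f"duplicate connection {c.key}")
            keys.add(c.key)

    @property
    def input_ids(self) -> list[int]:
        return [n.id for n in self.nodes if n.role == "input"]

    @property
    def output_ids(self) -> list[int]:
        """Output ids in ascending order (the action-selection tie-break order)."""
        return sorted(n.id for n in self.nodes if n.role == "output")

    @property
    def noninput_ids(self) -> list[int]:
        return sorted(n.id for n in self.nodes if n.role != "input")

    def node(self, node_id: int) -> NodeGene:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(f"no node with id {node_id}")

    def enabled_connections(self) -> list[ConnectionGene]:
        return [c for c in self.connections if c.enabled]

    def connection_keys(self, enabled_only: bool = True) -> list[tuple[int, int]]:
        return [c.key for c in self.connections if c.enabled or not enabled_only]

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "id": n.id,
                    "role": n.role,
                    "activation": n.activation,
                    "aggregation": n.aggregation,
                    "bias": n.bias,
                    "response": n.response,
                }
                for n in self.nodes
            ],
            "connections": [
                {
                    "source": c.source,
                    "target": c.target,
                    "weight": c.weight,
                    "enabled": c.enabled,
                }
                for c in self.connections
            ],
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Genome":
        nodes = [NodeGene(**n) for n in d["nodes"]]
        conns = [ConnectionGene(**c) for c in d["connections"]]
        return cls(nodes=nodes, connections=conns, metadata=dict(d.get("metadata", {})))

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "Genome":
        return cls.from_dict(json.loads(text))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "Genome":
        with open(path) as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# Lesion masks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LesionMask:
    """A set of severed connections (plus lesioned-node bookkeeping).

    Node lesions are realised as connection lesions; ``disabled_nodes`` only
    records which nodes a mask was built for.  Application is idempotent.
    """

    disabled_connections: frozenset = frozenset()
    disabled_nodes: frozenset = frozenset()

    def __or__(self, other: "LesionMask") -> "LesionMask":
        return LesionMask(
            self.disabled_connections | other.disabled_connections,
            self.disabled_nodes | other.disabled_nodes,
        )

    def validate_for(self, genome: Genome) -> None:
        enabled = set(genome.connection_keys(enabled_only=True))
        for key in self.disabled_connections:
            if key not in enabled:
                raise ValidationError(
                    f"masked connection {key} does not exist or is not enabled"
                )
        known = {n.id for n in genome.nodes}
        for nid in self.disabled_nodes:
            if nid not in known:
                raise ValidationError(f"masked node {nid} does not exist")


EMPTY_MASK = LesionMask()


def mask_connections(keys: Iterable[tuple[int, int]]) -> LesionMask:
    """Build a mask severing the given connection keys."""
    return LesionMask(disabled_connections=frozenset(tuple(k) for k in keys))


def prune_disabled(genome: Genome) -> Genome:
    """Return a copy of ``genome`` with the disabled connections removed."""
    genome.validate()
    return Genome(
        nodes=list(genome.nodes),
        connections=[c for c in genome.connections if c.enabled],
        metadata=dict(genome.metadata),
    )


def node_lesion_mask(genome: Genome, node_id: int, scope: str = "both") -> LesionMask:
    """Mask severing the enabled connections touching ``node_id``.

    ``scope`` selects ``"incoming"``, ``"outgoing"`` or ``"both"`` (default)
    connections; a self-loop is counted once in every scope it matches.
    """
    genome.node(node_id)  # raises KeyError for unknown ids
    if scope not in ("incoming", "outgoing", "both"):
        raise ValidationError(f"unknown lesion scope {scope!r}")
    keys = set()
    for c in genome.enabled_connections():
        incoming = c.target == node_id
        outgoing = c.source == node_id
        if (scope in ("incoming", "both") and incoming) or (
            scope in ("outgoing", "both") and outgoing
        ):
            keys.add(c.key)
    return LesionMask(frozenset(keys), frozenset({node_id}))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class NetworkState:
    """Post-activation values of all non-input nodes at the current step."""

    activations: dict[int, float]

    @classmethod
    def initial(cls, genome: Genome) -> "NetworkState":
        return cls({nid: 0.0 for nid in genome.noninput_ids})


@dataclass
class ActivityTrace:
    """node x time activity record plus the chosen action per timestep."""

    values: np.ndarray  # (T, n_nodes) post-activation values
    node_ids: list[int]
    chosen_actions: np.ndarray  # (T,) output node ids

    @property
    def T(self) -> int:
        return self.values.shape[0]

    def series(self, node_id: int) -> np.ndarray:
        return self.values[:, self.node_ids.index(node_id)]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=[str(i) for i in self.node_ids])
        df["chosen_action"] = self.chosen_actions
        df.index.name = "t"
        return df


class CompiledNetwork:
    """A genome + mask compiled to index arrays for batched evaluation.

    Evaluates B independent episodes in lock-step; used by :func:`run` (B=1)
    and by the task protocols, which batch hundreds of plays at once.
    """

    def __init__(self, genome: Genome, mask: LesionMask | None = None):
        mask = mask or EMPTY_MASK
        mask.validate_for(genome)
        self.genome = genome
        self.mask = mask
        self.input_ids = list(genome.input_ids)
        self.state_ids = list(genome.noninput_ids)
        in_index = {nid: k for k, nid in enumerate(self.input_ids)}
        st_index = {nid: k for k, nid in enumerate(self.state_ids)}
        self.output_pos = np.array(
            [st_index[i] for i in genome.output_ids], dtype=np.intp
        )
        self.output_ids = np.array(genome.output_ids, dtype=np.intp)

        self._nodes = []
        n_state, n_in = len(self.state_ids), len(self.input_ids)
        # Sum-aggregation nodes are evaluated as one matrix product per step;
        # other aggregations fall back to a per-node path.
        self._sum_pos: list[int] = []
        sum_acts: dict[str, list[int]] = {}
        W_st = np.zeros((n_state, n_state))
        W_in = np.zeros((n_state, n_in))
        bias_v = np.zeros(n_state)
        resp_v = np.ones(n_state)
        for nid in self.state_ids:
            gene = genome.node(nid)
            from_in: list[tuple[int, float]] = []
            from_st: list[tuple[int, float]] = []
            for c in genome.enabled_connections():
                if c.target != nid or c.key in mask.disabled_connections:
                    continue
                if c.source in in_index:
                    from_in.append((in_index[c.source], c.weight))
                else:
                    from_st.append((st_index[c.source], c.weight))
            pos = st_index[nid]
            bias_v[pos] = gene.bias
            resp_v[pos] = gene.response
            if gene.aggregation == "sum":
                self._sum_pos.append(pos)
                sum_acts.setdefault(gene.activation, []).append(pos)
                for i, w in from_in:
                    W_in[pos, i] = w
                for i, w in from_st:
                    W_st[pos, i] = w
            else:
                self._nodes.append(
                    (
                        pos,
                        ACTIVATIONS[gene.activation],
                        AGGREGATIONS[gene.aggregation],
                        gene.bias,
                        gene.response,
                        np.array([i for i, _ in from_in], dtype=np.intp),
                        np.array([w for _, w in from_in]),
                        np.array([i for i, _ in from_st], dtype=np.intp),
                        np.array([w for _, w in from_st]),
                    )
                )
        self._W_st_T = W_st.T.copy()
        self._W_in_T = W_in.T.copy()
        self._bias = bias_v
        self._resp = resp_v
        self._sum_groups = [
            (ACTIVATIONS[name], np.array(posns, dtype=np.intp))
            for name, posns in sum_acts.items()
        ]

    def step_batch(self, state: np.ndarray, inputs_t: np.ndarray) -> np.ndarray:
        """One synchronous update; ``state`` (B, n_state), ``inputs_t`` (B, n_in)."""
        new = np.empty_like(state)
        if self._sum_pos:
            z = self._bias + self._resp * (state @ self._W_st_T + inputs_t @ self._W_in_T)
            for act, posns in self._sum_groups:
                new[:, posns] = act(z[:, posns])
        for pos, act, agg, bias, response, ii, iw, si, sw in self._nodes:
            n_terms = ii.size + si.size
            if n_terms == 0:
                z1 = np.full(state.shape[0], bias)
            else:
                terms = np.empty((n_terms, state.shape[0]))
                if ii.size:
                    terms[: ii.size] = inputs_t[:, ii].T * iw[:, None]
                if si.size:
                    terms[ii.size:] = state[:, si].T * sw[:, None]
                z1 = bias + response * agg(terms)
            new[:, pos] = act(z1)
        return new

    def run_batch(self, inputs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Run B episodes of T steps; returns activations (B,T,n) and actions (B,T)."""
        if inputs.ndim != 3:
            raise ValidationError("inputs must have shape (B, T, n_inputs)")
        if inputs.shape[1] == 0:
            raise ValidationError("empty input series")
        if inputs.shape[2] != len(self.input_ids):
            raise ValidationError(
                f"series has {inputs.shape[2]} channels, genome has "
                f"{len(self.input_ids)} inputs"
            )
        if not np.isfinite(inputs).all():
            raise FloatingPointError("non-finite input value")
        B, T, _ = inputs.shape
        n = len(self.state_ids)
        acts = np.empty((B, T, n))
        state = np.zeros((B, n))
        for t in range(T):
            state = self.step_batch(state, inputs[:, t, :])
            acts[:, t, :] = state
        # winner-take-all over output nodes; argmax takes the first maximum,
        # and output_pos is in ascending-id order, so ties go to the lowest id
        winners = acts[:, :, self.output_pos].argmax(axis=2)
        actions = self.output_ids[winners]
        return acts, actions


def step(
    genome: Genome,
    state: NetworkState,
    inputs: Mapping[int, float],
    mask: LesionMask | None = None,
) -> NetworkState:
    """Advance the network one timestep (reference single-episode semantics).

    ``a_n(t) = act(bias + response * agg({w * x_src}))`` where input sources
    contribute their time-``t`` stimulus and non-input sources their ``t-1``
    activation; a node whose surviving input set is empty aggregates to 0.
    """
    mask = mask or EMPTY_MASK
    mask.validate_for(genome)
    missing = [i for i in genome.input_ids if i not in inputs]
    if missing:
        raise ValidationError(f"inputs missing for nodes {missing}")
    for i, v in inputs.items():
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite input on node {i}")
    prev = state.activations
    new: dict[int, float] = {}
    input_set = set(genome.input_ids)
    for nid in genome.noninput_ids:
        gene = genome.node(nid)
        terms = []
        for c in genome.enabled_connections():
            if c.target != nid or c.key in mask.disabled_connections:
                continue
            x = inputs[c.source] if c.source in input_set else prev[c.source]
            terms.append(c.weight * x)
        agg = AGGREGATIONS[gene.aggregation](np.array(terms)) if terms else 0.0
        z = gene.bias + gene.response * agg
        new[nid] = float(ACTIVATIONS[gene.activation](np.asarray(z)))
    return NetworkState(new)


def run(genome, input_series, mask: LesionMask | None = None) -> tuple[ActivityTrace, list[int]]:
    """Run an episode from the zero state; see :class:`ActivityTrace`.

    ``input_series`` is an object with ``values`` (T, n_inputs) and
    ``input_ids`` (see :mod:`netmsa.toytask`), or a bare (T, n_inputs) array
    in the genome's input order.
    """
    values = np.asarray(getattr(input_series, "values", input_series), dtype=float)
    if values.ndim != 2 or values.shape[0] == 0:
        raise ValidationError("input series must be a non-empty (T, n_inputs) matrix")
    ids = getattr(input_series, "input_ids", None)
    if ids is not None:
        order = [list(ids).index(i) for i in genome.input_ids]
        values = values[:, order]
    net = CompiledNetwork(genome, mask)
    acts, actions = net.run_batch(values[None, :, :])
    trace = ActivityTrace(acts[0], list(net.state_ids), actions[0])
    return trace, list(actions[0])
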