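"""Continuous-time stochastic Boolean networks (MaBoSS-style semantics).

Each node carries a logic expression over the other nodes plus flip rates.  A
node whose logic value disagrees with its current Boolean value is *unstable*
and flips 0->1 with rate_up or 1->0 with rate_down; waiting times are
exponential and the next flip is chosen by the Gillespie direct method, giving
an asynchronous continuous-time Markov chain over Boolean states.  Input nodes
are clamped: the simulator sets them and they never flip on their own.

Network file format (one declaration or node per line, ``#`` comments)::

    input TNF
    readout Proliferation
    readout Apoptosis
    readout NonACD
    NFkB : TNF & !Apoptosis & !NonACD : 0.005 : 0.02

i.e. ``name : logic : rate_up : rate_down`` with logic over ``& | ! ( )``,
node names and the constants 0/1.
"""

from __future__ import annotations

import re as _re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import _kernels
from ._kernels import OP_AND, OP_CONST, OP_NODE, OP_NOT, OP_OR

__all__ = [
    "BooleanNetwork",
    "NetworkState",
    "RandomStream",
    "parse_network",
    "load_network",
    "surrogate_network_path",
    "ctmc_step",
    "fate_readout",
    "NetworkParseError",
]

_READOUT_ROLES = {
    "proliferation": "proliferation",
    "apoptosis": "apoptosis",
    "nonacd": "nonacd",
    "nonad": "nonacd",
    "necrosis": "nonacd",
}

_TOKEN = _re.compile(r"\s*([A-Za-z_]\w*|[01]|[&|!()])")


class NetworkParseError(ValueError):
    pass


@dataclass
class BooleanNetwork:
    """Parsed network: node names, per-node flip rates, compiled logic."""

    names: list[str]
    rate_up: np.ndarray
    rate_down: np.ndarray
    is_input: np.ndarray           # bool per node (clamped externally)
    readouts: dict[str, int]       # role -> node index
    code: np.ndarray = field(repr=False)    # RPN opcodes, all nodes
    arg: np.ndarray = field(repr=False)
    starts: np.ndarray = field(repr=False)  # per-node slice into code/arg
    ends: np.ndarray = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def initial_state(self, on: tuple[str, ...] = ()) -> "NetworkState":
        values = np.zeros(self.n_nodes, dtype=np.uint8)
        for name in on:
            values[self.index(name)] = 1
        return NetworkState(values=values)


@dataclass
class NetworkState:
    """Boolean vector over the network's nodes plus a clock (minutes)."""

    values: np.ndarray
    clock: float = 0.0

    def get(self, net: BooleanNetwork, name: str) -> bool:
        return bool(self.values[net.index(name)])

    def set(self, net: BooleanNetwork, name: str, value: bool) -> None:
        self.values[net.index(name)] = np.uint8(value)


class RandomStream:
    """Counter-based random stream for one CTMC instance."""

    def __init__(self, seed: int, cell_id: int = 0):
        ids = np.array([cell_id], dtype=np.int64)
        self.key = _kernels.make_keys(int(seed), ids, _kernels.PUR_CTMC)[0]
        self.counter = np.uint64(0)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _tokenize(expr: str, lineno: int) -> list[str]:
    out, pos = [], 0
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if not m:
            raise NetworkParseError(
                f"line {lineno}: cannot tokenize logic at '{expr[pos:]}'")
        out.append(m.group(1))
        pos = m.end()
    return out


def _parse_expr(tokens: list[str], name_index: dict[str, int],
                lineno: int) -> tuple[list[int], list[int]]:
    """Recursive-descent OR > AND > NOT > atom; emits RPN (code, arg)."""
    pos = 0
    code: list[int] = []
    arg: list[int] = []

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def parse_or():
        parse_and()
        while peek() == "|":
            nonlocal pos
            pos += 1
            parse_and()
            code.append(OP_OR)
            arg.append(0)

    def parse_and():
        parse_not()
        while peek() == "&":
            nonlocal pos
            pos += 1
            parse_not()
            code.append(OP_AND)
            arg.append(0)

    def parse_not():
        nonlocal pos
        if peek() == "!":
            pos += 1
            parse_not()
            code.append(OP_NOT)
            arg.append(0)
        else:
            parse_atom()

    def parse_atom():
        nonlocal pos
        tok = peek()
        if tok is None:
            raise NetworkParseError(f"line {lineno}: unexpected end of logic")
        if tok == "(":
            pos += 1
            parse_or()
            if peek() != ")":
                raise NetworkParseError(f"line {lineno}: unbalanced '('")
            pos += 1
        elif tok in ("0", "1"):
            pos += 1
            code.append(OP_CONST)
            arg.append(int(tok))
        elif _re.fullmatch(r"[A-Za-z_]\w*", tok):
            pos += 1
            if tok not in name_index:
                raise NetworkParseError(
                    f"line {lineno}: unknown identifier '{tok}' in logic")
            code.append(OP_NODE)
            arg.append(name_index[tok])
        else:
            raise NetworkParseError(
                f"line {lineno}: unexpected token '{tok}'")

    parse_or()
    if pos != len(tokens):
        raise NetworkParseError(
            f"line {lineno}: trailing tokens {tokens[pos:]}")
    return code, arg


def parse_network(text: str) -> BooleanNetwork:
    """Parse the network document format into a validated BooleanNetwork."""
    inputs: list[str] = []
    readout_names: list[str] = []
    node_lines: list[tuple[int, str, str, str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("input "):
            inputs.append(line.split(None, 1)[1].strip())
            continue
        if line.startswith("readout "):
            readout_names.append(line.split(None, 1)[1].strip())
            continue
        parts = [p.strip() for p in line.split(":")]
        if len(parts) != 4:
            raise NetworkParseError(
                f"line {lineno}: expected 'name : logic : rate_up : "
                f"rate_down', got '{raw.strip()}'")
        node_lines.append((lineno, *parts))

    names = inputs + [p[1] for p in node_lines]
    if len(set(names)) != len(names):
        dup = [n for n in names if names.count(n) > 1][0]
        raise NetworkParseError(f"duplicate node name '{dup}'")
    name_index = {n: i for i, n in enumerate(names)}

    n = len(names)
    rate_up = np.zeros(n)
    rate_down = np.zeros(n)
    is_input = np.zeros(n, dtype=bool)
    for name in inputs:
        is_input[name_index[name]] = True

    code_all: list[int] = []
    arg_all: list[int] = []
    starts = np.zeros(n, dtype=np.int32)
    ends = np.zeros(n, dtype=np.int32)
    for lineno, name, logic, up_s, down_s in node_lines:
        i = name_index[name]
        try:
            rate_up[i] = float(up_s)
            rate_down[i] = float(down_s)
        except ValueError:
            raise NetworkParseError(
                f"line {lineno}: malformed rate for node '{name}'") from None
        if rate_up[i] < 0 or rate_down[i] < 0:
            raise NetworkParseError(
                f"line {lineno}: negative rate for node '{name}'")
        code, arg = _parse_expr(_tokenize(logic, lineno), name_index, lineno)
        starts[i] = len(code_all)
        code_all.extend(code)
        arg_all.extend(arg)
        ends[i] = len(code_all)

    readouts: dict[str, int] = {}
    for name in readout_names:
        if name not in name_index:
            raise NetworkParseError(f"readout '{name}' is not a node")
        role = _READOUT_ROLES.get(name.lower())
        if role is None:
            raise NetworkParseError(
                f"readout '{name}' does not match a fate role "
                f"(proliferation/apoptosis/NonACD)")
        readouts[role] = name_index[name]
    if readout_names and set(readouts) != {"proliferation", "apoptosis",
                                           "nonacd"}:
        raise NetworkParseError(
            "readout declarations must cover proliferation, apoptosis and "
            "NonACD")

    return BooleanNetwork(
        names=names, rate_up=rate_up, rate_down=rate_down,
        is_input=is_input, readouts=readouts,
        code=np.array(code_all, dtype=np.int32),
        arg=np.array(arg_all, dtype=np.int32),
        starts=starts, ends=ends)


def surrogate_network_path():
    """Path to the packaged surrogate cell-fate network file."""
    return resources.files("tumorpulse") / "networks" / "tnf_fate_surrogate.bnet"


def load_network(path=None) -> BooleanNetwork:
    """Load a network file; with no argument, the shipped surrogate."""
    if path is None:
        text = surrogate_network_path().read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return parse_network(text)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def ctmc_step(net: BooleanNetwork, state: NetworkState, dt: float,
              rng: RandomStream) -> NetworkState:
    """Advance the state by exactly dt of CTMC time (in place).

    Input nodes are treated as clamped at their current value.  If no node is
    unstable the values are unchanged and only the clock advances (absorbing
    states are legal).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    vals = state.values.reshape(1, -1)
    keys = np.array([rng.key], dtype=np.uint64)
    counters = np.array([rng.counter], dtype=np.uint64)
    _kernels.gillespie_window(
        vals, net.is_input, net.rate_up, net.rate_down, net.code, net.arg,
        net.starts, net.ends, float(dt), keys, counters)
    rng.counter = counters[0]
    state.clock += dt
    return state


def fate_readout(net: BooleanNetwork, state: NetworkState) -> str:
    """Map fate-node values to a phenotype label.

    Death readouts take precedence over proliferation; both death nodes ON
    indicates a broken network file and raises.
    """
    if not net.readouts:
        raise ValueError("network declares no readout nodes")
    apo = bool(state.values[net.readouts["apoptosis"]])
    nec = bool(state.values[net.readouts["nonacd"]])
    if apo and nec:
        raise ValueError(
            "both death readouts are ON; the network's fate logic is broken")
    if apo:
        return "apoptotic"
    if nec:
        return "necrotic"
    if state.values[net.readouts["proliferation"]]:
        return "proliferative"
    return "quiescent"
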