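"""Independent brute-force oracles used only by the test suite.

These deliberately take the slow, direct route (path enumeration, literal
formula evaluation) so they cannot share a bug with the production
algorithms they check.
"""

from __future__ import annotations

from itertools import combinations

from riversem.causal_graph import CausalDiagram


def dsep_path_enumeration(diagram: CausalDiagram, x: str, y: str, given) -> bool:
    """d-separation by enumerating every undirected simple path.

    A path is active given Z iff every intermediate node is open: a
    collider (both path arrows point into it) is open iff it or one of its
    descendants is in Z; any other node is open iff it is not in Z.
    x and y are d-separated iff no path between them is active.
    """
    given = frozenset(given)
    g = diagram.latent_expansion()  # bidirected arrows as explicit latents
    nodes = list(g.nodes)
    children: dict[str, set[str]] = {n: set() for n in nodes}
    neighbours: dict[str, list[tuple[str, bool]]] = {n: [] for n in nodes}
    for a, b in g.directed_arrows:
        children[a].add(b)
        neighbours[a].append((b, True))    # edge leaves a
        neighbours[b].append((a, False))   # edge enters b

    descendants: dict[str, set[str]] = {}
    for n in nodes:
        seen: set[str] = set()
        stack = [n]
        while stack:
            v = stack.pop()
            for c in children[v]:
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        descendants[n] = seen

    active_found = False

    def dfs(node: str, came_in: bool | None, visited: set[str]) -> None:
        # came_in: True iff the edge we arrived by pointed INTO `node`
        nonlocal active_found
        if active_found:
            return
        for nxt, leaves in neighbours[node]:
            if nxt in visited:
                continue
            if came_in is not None:
                collider = came_in and not leaves  # both arrows point into node
                if collider:
                    if not (node in given or descendants[node] & given):
                        continue
                elif node in given:
                    continue
            if nxt == y:
                active_found = True
                return
            # the edge points into nxt exactly when it leaves `node`
            dfs(nxt, leaves, visited | {nxt})

    dfs(x, None, {x})
    return not active_found


def all_pairs_and_conditioning(nodes, max_cond=2):
    """Every unordered pair with every conditioning set of size <= max_cond."""
    for x, y in combinations(nodes, 2):
        rest = [n for n in nodes if n not in (x, y)]
        for k in range(0, max_cond + 1):
            for z in combinations(rest, k):
                yield x, y, frozenset(z)
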