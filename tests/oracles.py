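"""Independent brute-force oracles used only by the test suite."""

from collections import deque


def bfs_min_moves(n_cups: int) -> int:
    """Fewest combine moves from all-loose to complete seriation, by BFS.

    States are frozensets of stacks (tuples, base first); a move lifts
    any top-contiguous segment of one stack onto any other stack. This
    deliberately re-derives the reachable state graph without using the
    package's state machine.
    """
    start = frozenset((r,) for r in range(1, n_cups + 1))
    goal = tuple(range(n_cups, 0, -1))
    seen = {start}
    queue = deque([(start, 0)])
    while queue:
        state, depth = queue.popleft()
        if len(state) == 1 and goal in state:
            return depth
        for src in state:
            for k in range(1, len(src) + 1):
                seg, rest = src[len(src) - k :], src[: len(src) - k]
                for tgt in state:
                    if tgt == src:
                        continue
                    nxt = set(state)
                    nxt.discard(src)
                    nxt.discard(tgt)
                    if rest:
                        nxt.add(rest)
                    nxt.add(tgt + seg)
                    frozen = frozenset(nxt)
                    if frozen not in seen:
                        seen.add(frozen)
                        queue.append((frozen, depth + 1))
    raise AssertionError("goal unreachable")
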