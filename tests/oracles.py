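"""Independent brute-force references the implementation is checked against.

These deliberately re-derive the rules from scratch (exhaustive enumeration
over candidate windows, naive fine-step integration) and share no code with
the package internals.
"""

from __future__ import annotations


def _r2(x: float) -> float:
    return round(x, 2)


def oracle_classify(
    workloads,
    lactates,
    tc1: float = 0.5,
    tc2: float = 0.4,
    window: int = 8,
    rise_epsilon: float = 0.1,
    cumulative_cap: float = 0.5,
):
    """Brute-force criterion classification.

    Returns ``(criterion, trigger_position, reference_position)`` with
    positions into the series, or ``("none", None, None)``.
    """
    n = len(workloads)
    candidates = []  # (trigger, priority, criterion, ref)

    # enumerate every workload increment and walk its constant segment
    for i in range(1, n):
        if not workloads[i] > workloads[i - 1]:
            continue
        ref = i - 1
        t = i
        k = 1
        while t < n and workloads[t] == workloads[i]:
            delta = _r2(lactates[t] - lactates[ref])
            if k == 1 and delta > tc1:
                candidates.append((t, 0, "TC1", ref))
                break
            if k <= window and delta > tc2 and not (k == 1 and delta > tc1):
                candidates.append((t, 1, "TC2", ref))
                break
            t += 1
            k += 1

    if candidates:
        trigger, _prio, criterion, ref = min(candidates)
        return criterion, trigger, ref

    # fallback: enumerate every 3-step window of slow constant-workload rises
    tc2a_hits = []
    for start in range(n - 3):
        ok = all(
            workloads[t] == workloads[t - 1]
            and _r2(lactates[t] - lactates[t - 1]) > rise_epsilon
            for t in range(start + 1, start + 4)
        )
        if ok and _r2(lactates[start + 3] - lactates[start]) <= cumulative_cap:
            tc2a_hits.append(start + 3)
    if tc2a_hits:
        trigger = min(tc2a_hits)
        return "TC2a", trigger, trigger - 3
    return "none", None, None


def oracle_relax(l0: float, target: float, tau: float, duration: float,
                 dt: float = 0.001) -> float:
    """Fine-step midpoint integration of dL/dt = (target - L) / tau."""
    steps = int(round(duration / dt))
    lac = l0
    for _ in range(steps):
        half = lac + 0.5 * dt * (target - lac) / tau
        lac += dt * (target - half) / tau
    return lac
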