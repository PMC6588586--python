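"""Independent brute-force reimplementation of the 20 characteristics.

Plain Python loops over samples, no numpy vectorisation, kept deliberately
naive so it can serve as an oracle for the production implementation.
"""

import math


def naive_features(traj, cfg):
    n = len(traj)
    dt = traj.dt
    H = traj.geometry.height_cm
    ok = [bool(v) for v in traj.valid_mask]
    dims = 3 if traj.y is not None else 2
    pts = []
    for i in range(n):
        if dims == 3:
            pts.append((float(traj.x[i]), float(traj.y[i]), float(traj.z[i])))
        else:
            pts.append((float(traj.x[i]), float(traj.z[i])))
    z = [float(v) for v in traj.z]

    # steps
    steps = {}
    for i in range(n - 1):
        if ok[i] and ok[i + 1]:
            d = tuple(pts[i + 1][k] - pts[i][k] for k in range(dims))
            length = math.sqrt(sum(c * c for c in d))
            steps[i] = {
                "vec": d,
                "len": length,
                "speed": length / dt,
                "bottom": (z[i] + z[i + 1]) / 2 < H / 2,
            }
    n_steps = len(steps)

    # accel / turn intervals (samples i, i+1, i+2 all valid)
    accels, turns = {}, {}
    for i in range(n - 2):
        if i in steps and i + 1 in steps:
            accels[i] = {
                "a": (steps[i + 1]["speed"] - steps[i]["speed"]) / dt,
                "bottom": z[i + 1] < H / 2,
            }
            v1, v2 = steps[i]["vec"], steps[i + 1]["vec"]
            n1, n2 = steps[i]["len"], steps[i + 1]["len"]
            if n1 > 0 and n2 > 0:
                cosang = sum(a * b for a, b in zip(v1, v2)) / (n1 * n2)
                cosang = max(-1.0, min(1.0, cosang))
            else:
                cosang = 1.0
            turns[i] = {"angle": math.degrees(math.acos(cosang)),
                        "out_speed": steps[i + 1]["speed"]}

    def mean(vals):
        vals = list(vals)
        return sum(vals) / len(vals) if vals else 0.0

    def vmax(vals):
        vals = list(vals)
        return max(vals) if vals else 0.0

    valid_time_s = n_steps * dt
    total = sum(s["len"] for s in steps.values())
    dist_bot = sum(s["len"] for s in steps.values() if s["bottom"])

    turn_count = sum(1 for t in turns.values() if t["angle"] >= cfg.turn_threshold_deg)
    fast_sharp = sum(1 for t in turns.values()
                     if t["angle"] > cfg.sharp_angle_deg and t["out_speed"] > cfg.fast_speed_cms)

    pos_acc = [a["a"] for a in accels.values() if a["a"] > 0]
    neg_acc = [-a["a"] for a in accels.values() if a["a"] < 0]

    n_ok = sum(ok)
    bottom_samples = sum(1 for i in range(n) if ok[i] and z[i] < H / 2)

    # occupancy grid
    g = cfg.grid_cells_per_axis
    extents = ((traj.geometry.width_cm, traj.geometry.depth_cm, traj.geometry.height_cm)
               if dims == 3 else (traj.geometry.width_cm, traj.geometry.height_cm))
    cells = set()
    for i in range(n):
        if not ok[i]:
            continue
        cell = tuple(min(max(int(math.floor(g * pts[i][k] / extents[k])), 0), g - 1)
                     for k in range(dims))
        cells.add(cell)
    explored = 100.0 * len(cells) / (g ** dims)

    # near lateral walls
    m = cfg.wall_margin_frac
    near = 0
    for i in range(n):
        if not ok[i]:
            continue
        x = pts[i][0]
        hit = x < m * traj.geometry.width_cm or x > (1 - m) * traj.geometry.width_cm
        if dims == 3:
            y = pts[i][1]
            hit = hit or y < m * traj.geometry.depth_cm or y > (1 - m) * traj.geometry.depth_cm
        near += hit

    return {
        "total_distance": total,
        "distance_top": total - dist_bot,
        "distance_bottom": dist_bot,
        "avg_speed": mean(s["speed"] for s in steps.values()),
        "avg_speed_top": mean(s["speed"] for s in steps.values() if not s["bottom"]),
        "avg_speed_bottom": mean(s["speed"] for s in steps.values() if s["bottom"]),
        "max_speed_top": vmax(s["speed"] for s in steps.values() if not s["bottom"]),
        "max_speed_bottom": vmax(s["speed"] for s in steps.values() if s["bottom"]),
        "pct_active": 100.0 * sum(1 for s in steps.values()
                                  if s["speed"] >= cfg.active_speed_cms) / n_steps,
        "avg_turns_per_min": turn_count / (valid_time_s / 60.0),
        "pct_fast_sharp_moves": 100.0 * fast_sharp / len(turns) if turns else 0.0,
        "avg_accel": mean(pos_acc),
        "avg_decel": mean(neg_acc),
        "avg_accel_top": mean(a["a"] for a in accels.values() if a["a"] > 0 and not a["bottom"]),
        "avg_accel_bottom": mean(a["a"] for a in accels.values() if a["a"] > 0 and a["bottom"]),
        "max_accel_top": vmax(a["a"] for a in accels.values() if a["a"] > 0 and not a["bottom"]),
        "max_accel_bottom": vmax(a["a"] for a in accels.values() if a["a"] > 0 and a["bottom"]),
        "pct_time_bottom": 100.0 * bottom_samples / n_ok,
        "pct_tank_explored": explored,
        "pct_time_near_walls": 100.0 * near / n_ok,
    }
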