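"""Independent naive reimplementations used as oracles in tests.

Everything here is double-loop, dictionary-based Python with no spatial
indexing and no shared code with the package internals.
"""

import math


def brute_force_contacts(frame, ligand_indices, protein_indices, cutoff):
    """Exhaustive double loop over all ligand-protein atom pairs."""
    out = []
    for i in ligand_indices:
        for j in protein_indices:
            d = math.dist(frame[i], frame[j])
            if d < cutoff:
                out.append((int(i), int(j), d))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def naive_profile(ensemble, cutoff):
    """Per-residue tallies recomputed from raw frames with dictionaries.

    Returns {ResidueID: dict with total/backbone/sidechain/frames_with_contact}.
    """
    tallies = {}
    for frame in ensemble.frames:
        touched = set()
        for i in ensemble.ligand_indices:
            for j in ensemble.protein_indices:
                d = math.dist(frame[i], frame[j])
                if d >= cutoff:
                    continue
                atom = ensemble.topology[j]
                rid = atom.residue_id
                rec = tallies.setdefault(
                    rid,
                    {"total": 0, "backbone": 0, "sidechain": 0, "frames_with_contact": 0},
                )
                rec["total"] += 1
                if atom.is_backbone:
                    rec["backbone"] += 1
                else:
                    rec["sidechain"] += 1
                touched.add(rid)
        for rid in touched:
            tallies[rid]["frames_with_contact"] += 1
    return tallies


def naive_differential(inh_tallies, nat_tallies, inh_frames, nat_frames):
    """Differential table rebuilt from the two raw per-residue count maps."""
    table = {}
    for rid in set(inh_tallies) | set(nat_tallies):
        imean = inh_tallies.get(rid, {"total": 0})["total"] / inh_frames
        nmean = nat_tallies.get(rid, {"total": 0})["total"] / nat_frames
        table[rid] = {"inhibitor_mean": imean, "natural_mean": nmean, "delta": imean - nmean}
    return table
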