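"""Simulator ground truth: event-log replay, closed-form calibrations,
determinism and the fixture presets."""

import numpy as np
import pytest

from viropan.datamodel import read_genome_set
from viropan.simulate import (
    SimConfig,
    genome_set_from_truth,
    make_fixture,
    replay_events,
    simulate_content,
    simulate_sequences,
    simulate_tree,
    tree_is_ultrametric,
)


def leaf_depths(tree):
    out = {}

    def rec(n, d):
        if not n.children:
            out[n.label] = d
        for c in n.children:
            rec(c, d + c.blen)

    rec(tree.root, 0.0)
    return out


def test_user_newick_passes_through():
    nwk = "((G01:1,G02:1):1,G03:2,G04:2);"
    cfg = SimConfig(seed=0, tree_newick=nwk)
    tree = simulate_tree(cfg)
    assert sorted(n.label for n in tree.tips()) == ["G01", "G02", "G03", "G04"]
    assert tree.to_newick().replace(" ", "") == nwk


def test_simulated_tree_has_requested_tips_and_is_ultrametric():
    for n_taxa in (4, 8, 13):
        cfg = SimConfig(seed=5, n_taxa=n_taxa, tree_height=1.0)
        tree = simulate_tree(cfg)
        assert len(tree.tips()) == n_taxa
        assert tree_is_ultrametric(tree, tol=1e-9)
        assert max(leaf_depths(tree).values()) == pytest.approx(1.0)


def test_tip_count_matches_pure_birth_expectation():
    """Unconditioned pure-birth (Yule) growth from 2 lineages: E[N(t)] =
    2 * exp(b*t).  Checked against the simulator's waiting-time mechanics by
    running many short conditioned simulations and measuring the time to
    reach n tips: E[T_n] = sum_{k=2}^{n-1} 1/(b*k)."""
    b = 1.0
    n_target = 8
    times = []
    for seed in range(500):
        rng = np.random.default_rng(seed)
        tree = simulate_tree(SimConfig(seed=seed, n_taxa=n_target, birth_rate=b), rng)
        times.append(max(leaf_depths(tree).values()))
    expected = sum(1.0 / (b * k) for k in range(2, n_target))
    se = np.std(times, ddof=1) / np.sqrt(len(times))
    assert abs(np.mean(times) - expected) < 3 * se


def test_no_event_limit_preserves_root_content():
    cfg = SimConfig(seed=2, n_taxa=6, loss_rate=0, dup_rate=0, denovo_rate=0, lgt_rate=0)
    rng = np.random.default_rng(2)
    tree = simulate_tree(cfg, rng)
    truth = simulate_content(tree, cfg, rng)
    assert list(truth.incidence.columns) == truth.root_families
    assert (truth.copy_number.to_numpy() == 1).all()


def test_loss_only_survival_matches_exponential():
    """mu > 0, everything else off: per-leaf survival frequency of 1000 root
    families within 3 standard errors of exp(-mu * path length)."""
    mu = 0.5
    cfg = SimConfig(seed=5, n_taxa=10, tree_height=1.0, n_root_families=1000,
                    loss_rate=mu, dup_rate=0, denovo_rate=0, lgt_rate=0)
    rng = np.random.default_rng(5)
    tree = simulate_tree(cfg, rng)
    truth = simulate_content(tree, cfg, rng)
    depths = leaf_depths(tree)
    for leaf in truth.incidence.index:
        p = np.exp(-mu * depths[leaf])
        freq = truth.incidence.loc[leaf, truth.root_families].mean()
        se = np.sqrt(p * (1 - p) / 1000)
        assert abs(freq - p) <= 3 * se


def test_duplication_only_keeps_presence_and_raises_copies():
    delta = 0.8
    cfg = SimConfig(seed=7, n_taxa=8, tree_height=1.0, n_root_families=400,
                    loss_rate=0, dup_rate=delta, denovo_rate=0, lgt_rate=0)
    rng = np.random.default_rng(7)
    tree = simulate_tree(cfg, rng)
    truth = simulate_content(tree, cfg, rng)
    assert (truth.incidence.to_numpy() == 1).all()
    depths = leaf_depths(tree)
    for leaf in truth.copy_number.index:
        mean_copy = truth.copy_number.loc[leaf].mean()
        expected = 1 + delta * depths[leaf]
        sd = np.sqrt(delta * depths[leaf] / 400)  # Poisson path total, 400 families
        assert abs(mean_copy - expected) <= 4 * sd


def test_event_log_replay_reproduces_truth(small_fixture):
    truth, _gs = small_fixture
    inc, copy = replay_events(truth)
    assert inc.equals(truth.incidence)
    assert copy.equals(truth.copy_number)


def test_family_absent_stays_absent_without_lgt():
    cfg = SimConfig(seed=9, n_taxa=8, tree_height=1.0, loss_rate=0.6,
                    dup_rate=0, denovo_rate=0, lgt_rate=0)
    rng = np.random.default_rng(9)
    tree = simulate_tree(cfg, rng)
    truth = simulate_content(tree, cfg, rng)
    # replay at internal nodes: once lost on a branch, no descendant has it
    lost_on = {}
    for rec in truth.events.to_dict("records"):
        lost_on.setdefault(rec["family"], set()).add(rec["branch"])

    def tips_below(label):
        node = next(n for n in tree.postorder() if n.label == label)
        out = []
        stack = [node]
        while stack:
            m = stack.pop()
            if m.children:
                stack.extend(m.children)
            else:
                out.append(m.label)
        return out

    for fam, branches in lost_on.items():
        for br in branches:
            for tip in tips_below(br):
                assert truth.incidence.loc[tip, fam] == 0


def test_zero_substitution_rate_gives_identical_family_members():
    cfg = SimConfig(seed=3, n_taxa=6, tree_height=1.0, subst_rate=0.0,
                    dup_rate=0.3, lgt_rate=0)
    rng = np.random.default_rng(3)
    tree = simulate_tree(cfg, rng)
    truth = simulate_sequences(simulate_content(tree, cfg, rng), cfg, rng)
    for fam, anc in truth.ancestral_sequences.items():
        for leaf, fams in truth.leaf_sequences.items():
            for s in fams.get(fam, []):
                assert s == anc


def test_pairwise_distance_matches_closed_form():
    """Uniform-replacement substitution: P(site unchanged over path T) =
    1/20 + (19/20) exp(-(20/19) rate T); empirical mean p-distance between
    two star tips over 200 families within 3 standard errors."""
    rate, t = 1.0, 0.3
    star = "(" + ",".join(f"G{i:02d}:{t}" for i in range(1, 5)) + ");"
    cfg = SimConfig(seed=11, tree_newick=star, n_root_families=200,
                    loss_rate=0, dup_rate=0, denovo_rate=0, lgt_rate=0,
                    subst_rate=rate, seq_len_range=(100, 100))
    rng = np.random.default_rng(11)
    tree = simulate_tree(cfg, rng)
    truth = simulate_sequences(simulate_content(tree, cfg, rng), cfg, rng)
    T = 2 * t
    p_same = 1 / 20 + (19 / 20) * np.exp(-(20 / 19) * rate * T)
    dists = []
    for fam in truth.root_families:
        a = truth.leaf_sequences["G01"][fam][0]
        b = truth.leaf_sequences["G02"][fam][0]
        dists.append(np.mean([x != y for x, y in zip(a, b)]))
    expected = 1 - p_same
    se = np.std(dists, ddof=1) / np.sqrt(len(dists))
    assert abs(np.mean(dists) - expected) <= 3 * se


def test_same_seed_gives_byte_identical_fixture(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    make_fixture("small", 7, d1)
    make_fixture("small", 7, d2)
    for p1 in sorted(d1.iterdir()):
        assert (d2 / p1.name).read_bytes() == p1.read_bytes()


def test_different_seeds_differ():
    t1, _, _ = make_fixture("small", 1)
    t2, _, _ = make_fixture("small", 2)
    assert not t1.incidence.equals(t2.incidence)


def test_unknown_preset_lists_presets():
    with pytest.raises(ValueError, match="small"):
        make_fixture("bogus", 1)


def test_reduction_preset_removes_configured_fraction():
    for seed in (1, 2):
        burst, _, _ = make_fixture("reduction", seed)
        twin, _, _ = make_fixture("small", seed)
        leaf = "G01"
        n_twin = int((twin.incidence.loc[leaf] > 0).sum())
        n_burst = int((burst.incidence.loc[leaf] > 0).sum())
        assert n_twin - n_burst == int(np.floor(0.16 * n_twin))


def test_fixture_roundtrips_through_genome_set_io(tmp_path, small_fixture):
    truth, gs = small_fixture
    _, gs2, files = make_fixture("small", 1, tmp_path)
    fastas = sorted(p for p in tmp_path.glob("G*.faa"))
    loaded = read_genome_set(fastas, tmp_path / "metadata.tsv")
    assert loaded.genome_ids == gs.genome_ids
    assert {o.orf_id: o.sequence for o in loaded.orfs.values()} == {
        o.orf_id: o.sequence for o in gs.orfs.values()
    }
    # genome summary counts equal the simulator's per-leaf copy totals
    for g in loaded.genomes:
        assert len(g.orf_ids) == int(truth.copy_number.loc[g.genome_id].sum())
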