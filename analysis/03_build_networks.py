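"""Build the three co-occurrence networks and export them.

Monopartite diagnosis, monopartite comorbidity, and the bipartite
diagnosis–comorbidity network, each as edge/node CSV plus GraphML/GEXF for
external visualization, together with the high-frequency pair table and
the partner-count tables from the bipartite graph.
"""

from pathlib import Path

from cadnet.network import (
    build_bipartite,
    build_monopartite,
    write_edge_list,
    write_gexf,
    write_graphml,
    write_node_list,
)
from cadnet.pipeline import cooccurrence_pairs, degree_tables
from cadnet.records import Category, load_cohort

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    cohort = load_cohort(OUT / "cohort.jsonl")
    nets = {
        "diagnosis": build_monopartite(cohort, Category.DIAGNOSIS),
        "comorbidity": build_monopartite(cohort, Category.COMORBIDITY),
        "bipartite": build_bipartite(cohort),
    }
    for mode, net in nets.items():
        net.validate()
        write_edge_list(net, OUT / f"network_{mode}_edges.csv")
        write_node_list(net, OUT / f"network_{mode}_nodes.csv")
        write_graphml(net, OUT / f"network_{mode}.graphml")
        write_gexf(net, OUT / f"network_{mode}.gexf")
        print(f"{mode}: {net.n_nodes} nodes, {net.n_edges} edges, "
              f"total weight {net.total_weight}")

    pairs = cooccurrence_pairs(nets["bipartite"], cutoff=10)
    pairs.to_csv(OUT / "table_pairs.csv", index=False)
    if len(pairs):
        top = pairs.iloc[0]
        print(f"strongest pair: {top.diagnosis} – {top.comorbidity} "
              f"(weight {top.weight}); {len(pairs)} pairs at weight >= 10")
    dia_t, com_t = degree_tables(nets["bipartite"], min_partners=10)
    dia_t.to_csv(OUT / "table_diagnosis_partners.csv", index=False)
    com_t.to_csv(OUT / "table_comorbidity_partners.csv", index=False)
    print(f"{len(dia_t)} diagnoses and {len(com_t)} comorbidities "
          f"with >= 10 cross-category partners")


if __name__ == "__main__":
    main()
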