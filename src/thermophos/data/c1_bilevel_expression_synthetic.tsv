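accession	contrast	fold_change	p_value
SPLC1_S204380	LOW_vs_OPT	2.0	0.01
SPLC1_S204380	HIGH_vs_OPT	2.0	0.01
SPLC1_S101160	LOW_vs_OPT	0.5	0.01
SPLC1_S101160	HIGH_vs_OPT	0.5	0.01
SPLC1_S208580	LOW_vs_OPT	0.5	0.01
SPLC1_S208580	HIGH_vs_OPT	2.0	0.01
SPLC1_S082160	LOW_vs_OPT	2.0	0.01
SPLC1_S082160	HIGH_vs_OPT	2.0	0.01
SPLC1_S102760	LOW_vs_OPT	2.0	0.01
SPLC1_S102760	HIGH_vs_OPT	0.5	0.01
SPLC1_S208940	LOW_vs_OPT	2.0	0.01
SPLC1_S208940	HIGH_vs_OPT	0.5	0.01
SPLC1_S034010	LOW_vs_OPT	0.5	0.01
SPLC1_S034010	HIGH_vs_OPT	0.5	0.01
SPLC1_S205200	LOW_vs_OPT	2.0	0.01
SPLC1_S205200	HIGH_vs_OPT	0.5	0.01
SPLC1_S540320	LOW_vs_OPT	0.5	0.01
SPLC1_S540320	HIGH_vs_OPT	0.5	0.01
SPLC1_S270810	LOW_vs_OPT	2.0	0.01
SPLC1_S270810	HIGH_vs_OPT	2.0	0.01
SPLC1_S430280	LOW_vs_OPT	0.5	0.01
SPLC1_S430280	HIGH_vs_OPT	2.0	0.01
SPLC1_S270380	LOW_vs_OPT	2.0	0.01
SPLC1_S270380	HIGH_vs_OPT	0.5	0.01
SPLC1_S082010	LOW_vs_OPT	0.5	0.01
SPLC1_S082010	HIGH_vs_OPT	0.5	0.01
SPLC1_S230960	LOW_vs_OPT	0.5	0.01
SPLC1_S230960	HIGH_vs_OPT	2.0	0.01
SPLC1_S040030	LOW_vs_OPT	0.5	0.01
SPLC1_S040030	HIGH_vs_OPT	2.0	0.01
SPLC1_S260960	LOW_vs_OPT	0.5	0.01
SPLC1_S260960	HIGH_vs_OPT	0.5	0.01
SPLC1_S051730	LOW_vs_OPT	2.0	0.01
SPLC1_S051730	HIGH_vs_OPT	0.5	0.01
SPLC1_S130380	LOW_vs_OPT	0.5	0.01
SPLC1_S130380	HIGH_vs_OPT	0.5	0.01
SPLC1_S171520	LOW_vs_OPT	0.5	0.01
SPLC1_S171520	HIGH_vs_OPT	2.0	0.01
SPLC1_S202870	LOW_vs_OPT	2.0	0.01
SPLC1_S202870	HIGH_vs_OPT	0.5	0.01
SPLC1_S120070	LOW_vs_OPT	2.0	0.01
SPLC1_S120070	HIGH_vs_OPT	0.5	0.01
SPLC1_S510820	LOW_vs_OPT	2.0	0.01
SPLC1_S510820	HIGH_vs_OPT	0.5	0.01
SPLC1_S205080	LOW_vs_OPT	2.0	0.01
SPLC1_S205080	HIGH_vs_OPT	2.0	0.01
SPLC1_S060060	LOW_vs_OPT	2.0	0.01
SPLC1_S060060	HIGH_vs_OPT	0.5	0.01
SPLC1_S207550	LOW_vs_OPT	2.0	0.01
SPLC1_S207550	HIGH_vs_OPT	0.5	0.01
SPLC1_S410530	LOW_vs_OPT	0.5	0.01
SPLC1_S410530	HIGH_vs_OPT	2.0	0.01
SPLC1_S542340	LOW_vs_OPT	0.5	0.01
SPLC1_S542340	HIGH_vs_OPT	0.5	0.01
SPLC1_S201490	LOW_vs_OPT	0.5	0.01
SPLC1_S201490	HIGH_vs_OPT	2.0	0.01
SPLC1_S240360	LOW_vs_OPT	2.0	0.01
SPLC1_S240360	HIGH_vs_OPT	2.0	0.01
SPLC1_S082540	LOW_vs_OPT	0.5	0.01
SPLC1_S082540	HIGH_vs_OPT	0.5	0.01
SPLC1_S203810	LOW_vs_OPT	0.5	0.01
SPLC1_S203810	HIGH_vs_OPT	0.5	0.01
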