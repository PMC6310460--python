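# Ligand atlas: nucleotide-like chemical components and gamma-phosphate
# mimic moieties, with atom-name substitutions onto canonical chain labels.
# substitutions: semicolon-separated SRC>DST pairs; '-' = identity mapping.
# classes: substrate, product, non_hydrolyzable, gamma_mimic
ligand_id	analog_class	substitutions
ATP	substrate	-
GTP	substrate	-
ADP	product	-
GDP	product	-
ANP	non_hydrolyzable	N3B>O3B
GNP	non_hydrolyzable	N3B>O3B
ACP	non_hydrolyzable	C3B>O3B
GCP	non_hydrolyzable	C3B>O3B
ASP	non_hydrolyzable	S1G>O1G
AGS	non_hydrolyzable	S1G>O1G
GSP	non_hydrolyzable	S1G>O1G
ALF	gamma_mimic	AL>PG;F1>O1G;F2>O2G;F3>O3G;F4>F4
AF3	gamma_mimic	AL>PG;F1>O1G;F2>O2G;F3>O3G
MGF	gamma_mimic	MG>PG;F1>O1G;F2>O2G;F3>O3G
BEF	gamma_mimic	BE>PG;F1>O1G;F2>O2G;F3>O3G
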