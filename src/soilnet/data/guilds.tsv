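name	rank	trophic_mode	guild	confidence
Fusarium	genus	Pathotroph	Plant Pathogen	Highly Probable
Gibberella	genus	Pathotroph	Plant Pathogen	Highly Probable
Verticillium	genus	Pathotroph	Plant Pathogen	Highly Probable
Alternaria	genus	Pathotroph-Saprotroph	Plant Pathogen	Possible
Rhizoctonia	genus	Pathotroph	Plant Pathogen	Highly Probable
Botrytis	genus	Pathotroph	Plant Pathogen	Highly Probable
Cladosporium	genus	Pathotroph-Saprotroph	Plant Pathogen	Possible
Nectriaceae	family	Pathotroph	Plant Pathogen	Probable
Ceratobasidiaceae	family	Pathotroph-Symbiotroph	Plant Pathogen	Probable
Pleosporaceae	family	Pathotroph-Saprotroph	Plant Pathogen	Possible
Sclerotiniaceae	family	Pathotroph	Plant Pathogen	Probable
Glomerellaceae	family	Pathotroph	Plant Pathogen	Probable
Ophiocordycipitaceae	family	Pathotroph	Animal Pathogen	Probable
Cordycipitaceae	family	Pathotroph	Animal Pathogen	Probable
Clavicipitaceae	family	Pathotroph	Animal Pathogen	Probable
Metarhizium	genus	Pathotroph	Animal Pathogen	Highly Probable
Beauveria	genus	Pathotroph	Animal Pathogen	Highly Probable
Trichoderma	genus	Saprotroph-Symbiotroph	Fungal Parasite	Probable
Hypocreaceae	family	Saprotroph	Undefined Saprotroph	Possible
Chaetomium	genus	Saprotroph	Undefined Saprotroph	Probable
Chaetomiaceae	family	Saprotroph	Undefined Saprotroph	Probable
Microascaceae	family	Saprotroph	Undefined Saprotroph	Probable
Lasiosphaeriaceae	family	Saprotroph	Dung Saprotroph	Probable
Sporormiaceae	family	Saprotroph	Dung Saprotroph	Probable
Trichocomaceae	family	Saprotroph	Undefined Saprotroph	Probable
Aspergillus	genus	Saprotroph	Undefined Saprotroph	Probable
Penicillium	genus	Saprotroph	Undefined Saprotroph	Probable
Mortierellaceae	family	Saprotroph	Undefined Saprotroph	Highly Probable
Mortierella	genus	Saprotroph	Undefined Saprotroph	Highly Probable
Cystofilobasidiaceae	family	Saprotroph	Undefined Saprotroph	Probable
Guehomyces	genus	Saprotroph	Undefined Saprotroph	Probable
Rhizophlyctidaceae	family	Saprotroph	Undefined Saprotroph	Probable
Rhizophlyctis	genus	Saprotroph	Undefined Saprotroph	Probable
Chytridiaceae	family	Saprotroph	Undefined Saprotroph	Possible
Glomeraceae	family	Symbiotroph	Arbuscular Mycorrhizal	Highly Probable
Tuberaceae	family	Symbiotroph	Ectomycorrhizal	Highly Probable
Tremellaceae	family	Pathotroph-Saprotroph	Fungal Parasite	Possible
Davidiellaceae	family	Saprotroph	Undefined Saprotroph	Possible
Trimorphomycetaceae	family	Saprotroph	Undefined Saprotroph	Possible
Piskurozymaceae	family	Saprotroph	Undefined Saprotroph	Possible
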