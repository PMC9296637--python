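otu_id	kingdom	phylum	genus	flag
OTU001	Bacteria	Firmicutes	Bacillus	
OTU002	Bacteria	Acidobacteria	Granulicella	
OTU003	Bacteria	Actinobacteria	Arthrobacter	
OTU004	Bacteria			unknown
OTU005	Bacteria	Acidobacteria	Granulicella	
OTU006	Bacteria	Proteobacteria	Noviherbaspirillum	
OTU007	Bacteria	Actinobacteria	Arthrobacter	
OTU008	Bacteria	Acidobacteria	Granulicella	
OTU009	Bacteria	Bacteroidetes	Chitinophaga	
OTU010	Bacteria	Bacteroidetes	Chitinophaga	
OTU011	Bacteria	Firmicutes	Paenibacillus	
OTU012	Bacteria	Acidobacteria	Granulicella	
OTU013	Bacteria	Acidobacteria	Granulicella	
OTU014	Bacteria	Firmicutes	Paenibacillus	
OTU015	Bacteria	Proteobacteria	Nordella	
OTU016	Bacteria	Bacteroidetes	Chitinophaga	
OTU017	Bacteria	Firmicutes	Paenibacillus	
OTU018	Bacteria	Bacteroidetes	Chitinophaga	
OTU019	Bacteria	Proteobacteria	Nordella	
OTU020	Bacteria	Firmicutes	Bacillus	
OTU021	Bacteria			unknown
OTU022	Bacteria	Actinobacteria	Marmoricola	
OTU023	Bacteria	Proteobacteria	Nordella	
OTU024	Bacteria	Acidobacteria	Granulicella	
OTU025	Bacteria	Firmicutes	Bacillus	
OTU026	Bacteria	Bacteroidetes	Flavobacterium	
OTU027	Bacteria	Firmicutes	Bacillus	
OTU028	Bacteria	Firmicutes	Paenibacillus	
OTU029	Bacteria	Proteobacteria	Variovorax	
OTU030	Bacteria	Bacteroidetes	Flavobacterium	
OTU031	Bacteria	Actinobacteria	Streptomyces	
OTU032	Bacteria	Bacteroidetes	Chitinophaga	
OTU033	Bacteria	Bacteroidetes	Chitinophaga	
OTU034	Bacteria	Bacteroidetes	Chitinophaga	
OTU035	Bacteria	Bacteroidetes	Flavobacterium	
OTU036	Bacteria	Proteobacteria	Noviherbaspirillum	
OTU037	Bacteria	Bacteroidetes	Chitinophaga	
OTU038	Bacteria	Proteobacteria	Pseudolabrys	
OTU039	Bacteria	Bacteroidetes	Chitinophaga	
OTU040	Bacteria	Bacteroidetes	Flavobacterium	
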