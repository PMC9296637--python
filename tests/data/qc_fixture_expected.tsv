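sample_id	OTU001	OTU002	OTU003	OTU005	OTU007	OTU008	OTU009	OTU010	OTU011	OTU012	OTU013	OTU015	OTU017	OTU018	OTU019	OTU020	OTU022	OTU023	OTU024	OTU025	OTU026	OTU027	OTU028	OTU029	OTU030	OTU031	OTU032	OTU033	OTU034	OTU036	OTU037	OTU038	OTU039	OTU040
S01	0.0107803902	0.0007253627	0.001875938	0.0046523262	0.0290645323	0.0018509255	0.0033266633	0.0477988994	0.0007753877	0.007903952	0.0047273637	0.0132316158	0.00010005	0.0104302151	0.0051275638	0.0055777889	0.0019009505	0.0137318659	0.0033016508	0.008104052	0.0105302651	0.0025512756	0.0012256128	0.0005002501	0.0923711856	0.4585792896	0.0242121061	0.0032766383	0.0004252126	0.0016008004	0.2230615308	0.0033016508	0.0004252126	0.0029514757
S02	0.0101396535	0.0005909614	0.0017728842	0.0053186526	0.0311032316	0.0018661939	0.0025193618	0.0486454543	0.0006531679	0.0091132469	0.0041367298	0.0147429318	0.0002177226	0.0099841374	0.0046343815	0.0052253429	0.0018039874	0.0139964542	0.0031103232	0.0081490467	0.0103262729	0.0026748779	0.0011197163	0.0006842711	0.0906037137	0.4547292464	0.0266554695	0.0037012846	0.0004665485	0.0014929551	0.2223881061	0.0036079749	0.0003732388	0.0034524587
S03	0.0111423109	0.0007169315	0.0018520731	0.0050483929	0.0295734257	0.001822201	0.0023598996	0.0497371251	0.0005675708	0.0086927948	0.0044808221	0.0123969411	8.96164e-05	0.0094694707	0.0051380093	0.005675708	0.0021507946	0.0136216991	0.003644402	0.0094395985	0.0108734616	0.0031067033	0.001224758	0.0003883379	0.0914087705	0.4534591946	0.0266459553	0.0037340184	0.0005376986	0.0014039909	0.222398136	0.0037340184	0.0004480822	0.0030170869
S05	0.0115106868	0.0006542917	0.0014782145	0.0052101003	0.0297339214	0.0021325062	0.0030048951	0.0497019338	0.0004846605	0.0090146852	0.0037561188	0.013740125	0.0002665633	0.0096205108	0.004919304	0.0051374013	0.0016720787	0.0139339892	0.002956429	0.008845054	0.0106867639	0.0025444676	0.0014539815	0.0004846605	0.0925701546	0.4526486696	0.0260505016	0.0033926235	0.0005815926	0.0015024475	0.2235496535	0.0033199244	0.0003150293	0.0031260602
S06	0.0117921198	0.000706115	0.0016946759	0.0061432001	0.0282445982	0.0017652874	0.0028950713	0.0485807089	0.0009179494	0.0080497105	0.0040954667	0.0132749612	0.0002118345	0.0100268324	0.0050134162	0.0056489196	0.0011297839	0.0149696371	0.0028950713	0.008543991	0.0088970484	0.0024714023	0.0007767265	0.0003530575	0.0908769948	0.4553735348	0.0254907499	0.0026832368	0.000564892	0.0019771219	0.2260980088	0.0033893518	0.000141223	0.0043073012
S07	0.0106883283	0.0005441331	0.0014769326	0.0047805978	0.0311321855	0.0017878658	0.002098799	0.0501768433	0.0006995997	0.0070348634	0.0042364647	0.0127482607	0.0001554666	0.0101053286	0.0048971977	0.0047805978	0.0017101325	0.0139142602	0.0034591317	0.0094057289	0.012165261	0.0025263322	0.0011659995	0.0004275331	0.0911422908	0.4594815189	0.0247969218	0.0034979984	0.000777333	0.0013603327	0.2193244976	0.003653465	0.0004275331	0.0034202651
S08	0.011708949	0.001140482	0.001647363	0.0053475936	0.0304635426	0.0018501153	0.0026357807	0.049091416	0.0007096333	0.0084649112	0.0040043592	0.0142180095	0.0002027524	0.0096053932	0.0050941531	0.0052462174	0.001698051	0.0140659452	0.0035988544	0.0086930076	0.0114555085	0.002762501	0.0009630737	0.0004055047	0.0887801911	0.459259447	0.0258255823	0.0034467902	0.0007349773	0.0017233951	0.2189725524	0.002762501	0.0004815369	0.0029399093
S09	0.0109856731	0.0004050018	0.0014681314	0.0052143978	0.0287045006	0.0016706323	0.0023287602	0.0504227206	0.000455627	0.0095175416	0.0044043943	0.0131625576	0.0003037513	0.0102262947	0.0053662735	0.0051637726	0.0020756341	0.0153900673	0.0029362628	0.0088087885	0.0106819217	0.0016706323	0.0011137549	0.000455627	0.0916822761	0.4575001266	0.0245026072	0.0042018934	0.0004050018	0.0018731332	0.2208272161	0.0033918898	0.0004050018	0.002278135
S10	0.0099604222	0.0005277045	0.0013192612	0.0051451187	0.0296833773	0.0020448549	0.0031662269	0.0484828496	0.0011873351	0.0081134565	0.0048812665	0.0132585752	0.0003298153	0.0111477573	0.0057387863	0.0056728232	0.0015171504	0.0139841689	0.0028364116	0.0087730871	0.011939314	0.0024406332	0.0008575198	0.0003957784	0.0897097625	0.4620712401	0.0245382586	0.0029023747	0.0002638522	0.0013192612	0.2192612137	0.0027704485	0.0002638522	0.0034960422
S11	0.0106591255	0.0007251106	0.0018127764	0.0055833515	0.0293669785	0.0018852875	0.0031179755	0.0497425857	0.0008701327	0.0096439707	0.0052207962	0.0128344573	0.0004350663	0.0103690813	0.0051482851	0.0058733957	0.0021028207	0.0161699659	0.0026829091	0.0081212385	0.0108041476	0.0026103981	0.0011601769	0.0007251106	0.090058734	0.4526140236	0.0287143789	0.0038430861	0.0007976216	0.0007976216	0.219055906	0.0031904865	0.0003625553	0.0029004423
S12	0.0108854058	0.0008327633	0.0016952681	0.0053237367	0.0301876692	0.0019926836	0.002617256	0.0485679446	0.0005650894	0.0088629807	0.0036284686	0.013294471	0.0001784493	0.0109448889	0.005175029	0.0052642536	0.0021711329	0.012640157	0.0031823454	0.008119442	0.0105879904	0.0024982899	0.0012788865	0.0002379324	0.0945186331	0.4576331678	0.0240311691	0.0037474348	0.0004758647	0.0014870773	0.2206822711	0.0032715701	0.000327157	0.0030931208
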