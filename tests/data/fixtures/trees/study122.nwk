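(((t001:8.4853697722471466,(t015:0.77057869046084704,t110:0.77057869046084704):7.7147910817862995):2.7762079083899107,(t006:7.1470392313158069,(t022:0.94980899473879088,t104:0.94980899473879088):6.197230236577016):4.11453844932125):4.9384223193629397,(((((t002:0.35365845527438122,t120:0.35365845527438122):6.5241642280095409,((t026:3.2218928647387268,t067:3.2218928647387268):3.1677449682919274,(t033:4.4160621882573556,((t056:0.87167507561329083,t107:0.87167507561329083):1.1380775951566973,t084:2.0097526707699882):2.4063095174873679):1.9735756447732986):0.48818485025326819):3.4569575640277965,t011:10.33478024731172):0.2890323428341704,((t010:0.83723434972205324,t108:0.83723434972205324):3.5192090947942636,(t058:1.5580443734849829,t092:1.5580443734849829):2.7983990710313336):6.2673691456295728):4.8475537410215059,(((((t003:2.2343816590620031,t079:2.2343816590620031):1.3018353792962143,t064:3.5362170383582172):0.91384081446764232,t054:4.4500578528258599):6.6259535542084826,(((t008:4.7048623303364536,(t051:4.5737372712449416,((t053:1.0709502822360593,t100:1.0709502822360593):2.5681848484612488,(t062:0.11199953541930724,t122:0.11199953541930724):3.5271355952780006):0.93460214054763358):0.13112505909151184):4.479607636006758,(((t013:7.3448097801084709,(((t018:4.4036529346753568,t057:4.4036529346753568):0.59848341842530239,t049:5.0021363531006591):1.5003316139772649,(((t030:1.1906432334812054,(t097:0.72705530098552384,t112:0.72705530098552384):0.46358793249568159):0.9291031822952166,t082:2.1197464157764219):4.2328679252472439,((t035:1.158506555164909,t099:1.158506555164909):3.4739828894151663,t052:4.6324894445800755):1.7201248964435909):0.14985362605425817):0.84234181303054656):0.56048706643127921,((((t017:5.1881979300135042,(t046:2.8324053089248333,t073:2.8324053089248333):2.3557926210886704):1.5396788026817037,(t028:5.1688202565388677,t047:5.1688202565388677):1.5590564761563395):0.15190657199964577,((((t025:0.72194799881296023,t113:0.72194799881296023):3.9995388947065744,(t050:2.2173399418599908,t080:2.2173399418599908):2.504146951659544):1.2375117278265928,(t041:5.6030135229970872,(t043:0.32141905114716146,t121:0.32141905114716146):5.2815944718499255):0.35598509834904046):0.80398997600533517,(((t027:0.80246515819929587,t109:0.80246515819929587):5.5283429380992475,(t037:2.1287013923329936,t081:2.1287013923329936):4.2021067039655504):0.0099965219427573786,t036:6.3408046182413011):0.42218397911016153):0.11679470734339061):0.30081743667539895,(((t019:6.2498542936443924,((t038:2.5179295878572217,(t078:2.0151551735416002,t083:2.0151551735416002):0.50277441431562131):0.5846047709360056,t068:3.102534358793227):3.1473199348511649):0.30259794304695853,((t029:4.0866327826700459,(t059:1.8302471065297672,(t089:1.1665933939721189,t098:1.1665933939721189):0.66365371255764816):2.2563856761402792):2.4150476292615921,((((t031:2.8261450112159521,t074:2.8261450112159521):1.5986856986183193,(t055:2.8090371421564861,((t075:0.44950224866213478,t117:0.44950224866213478):1.3190334619471282,((t090:0.46600918034952937,t116:0.46600918034952937):0.55375819185139763,t101:1.0197673722009271):0.7487683384083359):1.0405014315472234):1.6157935676777853):1.0310890556740262,t045:5.4559197655082974):0.9131964145243332,(t034:4.0199411569311607,((t060:2.8620351719737869,t072:2.8620351719737869):0.041203861812879716,t071:2.9032390337866665):1.1167021231444947):2.3491750231014699):0.13256423189900743):0.050771824759712092):0.46996687544095311,(t024:3.4105039776670156,t065:3.4105039776670156):3.611915134465288):0.15818162923794857):0.7246961051694979):1.2415051936293773,t014:9.1468020401691277):0.037667926174083793):0.95096714712238373,((t012:5.1621418969079675,(t048:3.3893369875718173,((t066:1.9236118294631901,t085:1.9236118294631901):1.1079629628586396,((t069:0.67737949360872207,t114:0.67737949360872207):0.07279425756481353,t111:0.75017375117353557):2.2814010411482939):0.35776219524998776):1.7728049093361504):1.892263834284708,t023:7.0544057311926753):3.081031382272919):0.94057429356874678):2.1634594774105071,(((t004:2.9384910523226706,((t070:1.501595666731286,((t093:0.92968716993004863,t106:0.92968716993004863):0.088631432667859417,(t102:0.43566004910124045,t118:0.43566004910124045):0.58265855349666762):0.4832770641333779):0.38590668773095027,t087:1.8875023544622362):1.0509886978604346):7.886633908942704,(t009:2.7966318429115247,t076:2.7966318429115247):8.0284931183538504):0.89753364005596858,((t005:6.1408949536898314,(t039:1.8879425294176115,t086:1.8879425294176115):4.2529524242722196):5.0653810114611346,((t007:3.5652052623004766,(t063:0.39986609815703172,t119:0.39986609815703172):3.165339164143445):4.6633910009863424,(t016:7.1749551916976193,(((((t020:0.51771646983904396,t115:0.51771646983904396):0.48547057293359663,t103:1.0031870427726406):0.83601958552338718,(t088:1.5891769760459322,(t091:1.3639286967279138,t094:1.3639286967279138):0.22524827931801836):0.25002965225009566):4.595155109389407,((t032:2.559054477751185,((t077:0.93397482069109172,t105:0.93397482069109172):0.41331792344289281,t095:1.3472927441339846):1.2117617336172006):3.4413523303879479,((t040:3.6655467963401853,t061:3.6655467963401853):1.835086967334953,t044:5.5006337636751388):0.49977304446399451):0.43395492954630149):0.72202730097015677,((t021:1.3032030460094324,t096:1.3032030460094324):4.4905427699526852,t042:5.7937458159621178):1.3626432226934739):0.018566153042027685):1.0536410715892):2.9776797018641465):0.51638263617037683):1.5168122831235062):2.2318954467225467):0.72863366883260183);
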